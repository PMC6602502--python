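<?xml version="1.0" encoding="UTF-8"?>
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema" elementFormDefault="unqualified">
  <xs:simpleType name="hexColor">
    <xs:restriction base="xs:string">
      <xs:pattern value="#[0-9A-Fa-f]{6}"/>
    </xs:restriction>
  </xs:simpleType>
  <xs:element name="ogconfig">
    <xs:complexType>
      <xs:choice minOccurs="0" maxOccurs="unbounded">
        <xs:element name="class">
          <xs:complexType>
            <xs:attribute name="id" type="xs:string" use="required"/>
            <xs:attribute name="color" type="hexColor"/>
            <xs:attribute name="label" type="xs:string"/>
            <xs:attribute name="enabled" type="xs:boolean"/>
          </xs:complexType>
        </xs:element>
        <xs:element name="gene">
          <xs:complexType>
            <xs:attribute name="name" type="xs:string" use="required"/>
            <xs:attribute name="color" type="hexColor"/>
            <xs:attribute name="product" type="xs:string"/>
            <xs:attribute name="class" type="xs:string"/>
          </xs:complexType>
        </xs:element>
        <xs:element name="featurekey">
          <xs:complexType>
            <xs:attribute name="key" type="xs:string" use="required"/>
            <xs:attribute name="class" type="xs:string" use="required"/>
          </xs:complexType>
        </xs:element>
      </xs:choice>
    </xs:complexType>
  </xs:element>
</xs:schema>
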
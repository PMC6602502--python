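{
  "version": 1,
  "plastid": [
    {"id": "photosystem_I", "label": "photosystem I", "color": "#1F6E43", "patterns": ["psa*"], "keys": []},
    {"id": "photosystem_II", "label": "photosystem II", "color": "#66B032", "patterns": ["psb*"], "keys": []},
    {"id": "cytochrome_complex", "label": "cytochrome b6/f complex", "color": "#7A6A28", "patterns": ["pet*"], "keys": []},
    {"id": "atp_synthase", "label": "ATP synthase", "color": "#B2552D", "patterns": ["atp*"], "keys": []},
    {"id": "nadh_dehydrogenase", "label": "NADH dehydrogenase", "color": "#FFD54F", "patterns": ["ndh*"], "keys": []},
    {"id": "rubisco", "label": "RubisCO large subunit", "color": "#2E8B57", "patterns": ["rbc*"], "keys": []},
    {"id": "rna_polymerase", "label": "RNA polymerase", "color": "#AE2D68", "patterns": ["rpo*"], "keys": []},
    {"id": "ribosomal_protein_SSU", "label": "ribosomal proteins (SSU)", "color": "#D9A54A", "patterns": ["rps*"], "keys": []},
    {"id": "ribosomal_protein_LSU", "label": "ribosomal proteins (LSU)", "color": "#8D6E3F", "patterns": ["rpl*"], "keys": []},
    {"id": "clpP_matK", "label": "clpP, matK", "color": "#C2185B", "patterns": ["clp*", "mat*"], "keys": []},
    {"id": "other_protein", "label": "other genes", "color": "#5C6BC0", "patterns": ["ccsA", "cemA", "accD", "infA"], "keys": []},
    {"id": "hypothetical", "label": "hypothetical reading frames (ycf)", "color": "#9E9E9E", "patterns": ["ycf*", "orf*"], "keys": []},
    {"id": "trna", "label": "transfer RNAs", "color": "#1A237E", "patterns": ["trn*"], "keys": ["tRNA"]},
    {"id": "rrna", "label": "ribosomal RNAs", "color": "#C62828", "patterns": ["rrn*"], "keys": ["rRNA"]},
    {"id": "intron", "label": "introns", "color": "#FFFFFF", "patterns": [], "keys": ["intron"]},
    {"id": "origin_of_replication", "label": "origin of replication", "color": "#616161", "patterns": ["oriA", "oriB"], "keys": ["rep_origin"]},
    {"id": "operon", "label": "polycistronic transcripts", "color": "#90A4AE", "patterns": [], "keys": ["prim_transcript", "operon"]},
    {"id": "dloop", "label": "D-loop", "color": "#BDBDBD", "patterns": [], "keys": ["D-loop"]},
    {"id": "other", "label": "other", "color": "#B0BEC5", "patterns": [], "keys": []}
  ],
  "mitochondrial": [
    {"id": "complex_I", "label": "complex I (NADH dehydrogenase)", "color": "#66B032", "patterns": ["nad*"], "keys": []},
    {"id": "complex_II", "label": "complex II (succinate dehydrogenase)", "color": "#F2C249", "patterns": ["sdh*"], "keys": []},
    {"id": "complex_III", "label": "complex III (ubiquinol cytochrome c reductase)", "color": "#AE2D68", "patterns": ["cob*"], "keys": []},
    {"id": "complex_IV", "label": "complex IV (cytochrome c oxidase)", "color": "#7E57C2", "patterns": ["cox*"], "keys": []},
    {"id": "complex_V", "label": "complex V (ATP synthase)", "color": "#B2552D", "patterns": ["atp*"], "keys": []},
    {"id": "ccb", "label": "cytochrome c biogenesis", "color": "#00838F", "patterns": ["ccm*", "ccb*"], "keys": []},
    {"id": "ribosomal_protein", "label": "ribosomal proteins", "color": "#D9A54A", "patterns": ["rps*", "rpl*"], "keys": []},
    {"id": "maturase", "label": "maturases", "color": "#C2185B", "patterns": ["mat*", "mttB"], "keys": []},
    {"id": "trna", "label": "transfer RNAs", "color": "#1A237E", "patterns": ["trn*"], "keys": ["tRNA"]},
    {"id": "rrna", "label": "ribosomal RNAs", "color": "#C62828", "patterns": ["rrn*"], "keys": ["rRNA"]},
    {"id": "intron", "label": "introns", "color": "#FFFFFF", "patterns": [], "keys": ["intron"]},
    {"id": "origin_of_replication", "label": "origin of replication", "color": "#616161", "patterns": [], "keys": ["rep_origin"]},
    {"id": "operon", "label": "polycistronic transcripts", "color": "#90A4AE", "patterns": [], "keys": ["prim_transcript", "operon"]},
    {"id": "dloop", "label": "D-loop", "color": "#BDBDBD", "patterns": [], "keys": ["D-loop"]},
    {"id": "other", "label": "other", "color": "#B0BEC5", "patterns": [], "keys": []}
  ],
  "other": [
    {"id": "trna", "label": "transfer RNAs", "color": "#1A237E", "patterns": ["trn*"], "keys": ["tRNA"]},
    {"id": "rrna", "label": "ribosomal RNAs", "color": "#C62828", "patterns": ["rrn*"], "keys": ["rRNA"]},
    {"id": "coding", "label": "protein-coding genes", "color": "#4472C4", "patterns": ["*"], "keys": []},
    {"id": "intron", "label": "introns", "color": "#FFFFFF", "patterns": [], "keys": ["intron"]},
    {"id": "origin_of_replication", "label": "origin of replication", "color": "#616161", "patterns": [], "keys": ["rep_origin"]},
    {"id": "operon", "label": "polycistronic transcripts", "color": "#90A4AE", "patterns": [], "keys": ["prim_transcript", "operon"]},
    {"id": "dloop", "label": "D-loop", "color": "#BDBDBD", "patterns": [], "keys": ["D-loop"]},
    {"id": "other", "label": "other", "color": "#B0BEC5", "patterns": [], "keys": []}
  ]
}
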
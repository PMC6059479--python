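{
  "DNA binding": [
    "DNA-templated transcription, initiation",
    "DNA-templated transcription, elongation",
    "DNA-templated transcription, termination",
    "transcription from RNA polymerase I promoter",
    "transcription from RNA polymerase II promoter",
    "chromatin organization",
    "histone modification",
    "DNA replication",
    "DNA recombination",
    "DNA repair",
    "cellular response to DNA damage stimulus",
    "regulation of DNA metabolic process",
    "nuclear transport",
    "chromosome segregation"
  ],
  "RNA binding or processing": [
    "mRNA processing",
    "rRNA processing",
    "tRNA processing",
    "RNA modification",
    "RNA splicing",
    "RNA catabolic process"
  ],
  "metabolism": [
    "carbohydrate metabolic process",
    "cofactor metabolic process",
    "nucleobase-containing small-molecule metabolic process",
    "monocarboxylic acid metabolic process",
    "cellular amino acid metabolic process",
    "generation of precursor metabolites and energy",
    "oligosaccharide metabolic process",
    "lipid metabolic process"
  ]
}
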
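# Default bespoke GO SLIM: 12 high-level terms covering nuclear and
# nucleic-acid-related processes, functions and the nucleus component,
# used to classify complexes via descendant closure.
slim_roots:
  - id: "GO:0006139"
    name: "nucleobase-containing compound metabolic process"
    namespace: biological_process
  - id: "GO:0010467"
    name: "gene expression"
    namespace: biological_process
  - id: "GO:0051276"
    name: "chromosome organization"
    namespace: biological_process
  - id: "GO:0006974"
    name: "cellular response to DNA damage stimulus"
    namespace: biological_process
  - id: "GO:0071826"
    name: "ribonucleoprotein complex subunit organization"
    namespace: biological_process
  - id: "GO:0006997"
    name: "nucleus organization"
    namespace: biological_process
  - id: "GO:0005634"
    name: "nucleus"
    namespace: cellular_component
  - id: "GO:0003676"
    name: "nucleic acid binding"
    namespace: molecular_function
  - id: "GO:0140098"
    name: "catalytic activity, acting on RNA"
    namespace: molecular_function
  - id: "GO:0140110"
    name: "transcription regulator activity"
    namespace: molecular_function
  - id: "GO:0140097"
    name: "catalytic activity, acting on DNA"
    namespace: molecular_function
  - id: "GO:0045182"
    name: "translation regulator activity"
    namespace: molecular_function
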
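"""Default keyword lists for the functional screen.

Five functional themes drive candidate shortlisting in glomerular-disease
work: immune/autoimmune processes, blood-pressure regulation, vascular
injury, oxidative stress and extracellular-matrix remodelling.  Each maps
to a list of phrases matched case-insensitively as substrings of a gene's
functional-annotation text.  Users can supply their own mapping (YAML/JSON)
to replace these.
"""

DEFAULT_KEYWORDS: dict[str, list[str]] = {
    "immunity_autoimmunity": [
        "immune response",
        "autoimmun",
        "complement activation",
        "inflammat",
        "antigen presentation",
        "immunoglobulin",
    ],
    "blood_pressure_regulation": [
        "blood pressure",
        "angiotensin",
        "renin",
        "vasoconstrict",
        "vasodilat",
        "natriuresis",
    ],
    "vascular_injury": [
        "vascular injury",
        "endothelial damage",
        "platelet activation",
        "thrombosis",
        "vessel wall",
        "coagulation",
    ],
    "oxidative_stress": [
        "oxidative stress",
        "reactive oxygen species",
        "redox",
        "superoxide",
        "peroxidase",
        "heme scavenging",
    ],
    "ecm_remodelling": [
        "extracellular matrix",
        "collagen",
        "matrix remodel",
        "matrix metalloproteinase",
        "basement membrane",
        "integrin",
    ],
}

# Innocuous annotation phrases used by the simulator for background genes.
NEUTRAL_PHRASES: list[str] = [
    "ribosome biogenesis",
    "mRNA splicing regulation",
    "tRNA aminoacylation",
    "chromatin organisation",
    "microtubule nucleation",
    "Golgi vesicle budding",
    "nucleotide salvage",
    "proteasomal catabolism",
    "ciliary assembly",
    "telomere maintenance",
]
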
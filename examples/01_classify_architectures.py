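"""Classify a handful of domain architectures against the rule catalog.

Each protein is summarised by its ordered N->C domain-name list; the
catalog maps it to a hierarchical label (class / subclass / subdivision).
"""

from setfam import Architecture, classify_architecture, load_catalog

catalog = load_catalog()

architectures = [
    ["AWS", "SET"],                                  # minimal Ash backbone
    ["AWS", "SET", "PostSET"],                       # + C-terminal PostSET
    ["PHD", "PHD", "PHD", "AWS", "SET"],             # triple-PHD Ash
    ["PWWP", "FYR", "PHD", "PHD", "SET"],            # Trx reader stack
    ["SRA", "PreSET", "SET", "SET"],                 # tandem-SET Su(var)
    ["TCR", "PreSET", "SET"],                        # an E(z) variant
    ["Rubis_subs_bind", "SET"],                      # Rubisco-LSMT type
    ["AWS", "SET", "TUDOR"],                         # extra domain: no effect
    ["SET"],                                         # bare SET -> homology
]

for domains in architectures:
    res = classify_architecture(Architecture(domains), catalog)
    print(f"{'-'.join(domains):45s} -> {str(res.label):10s}"
          f" ({res.label.family}, {res.match_kind})")

print()
print("A label like II-2A reads: class II (Ash), subclass 2, subdivision A.")
print("Bare-SET proteins are provisional Orphans until the homology"
      " fallback places them (see classify_all).")
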
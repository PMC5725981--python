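"""Phyletic profiles and earliest lineage appearances of domains.

The catalog carries a 16-species +/- profile per architecture type;
projecting a domain onto the configured lineage order (glaucophyta ->
angiosperms) dates its earliest appearance within a family context.
"""

from setfam import earliest_appearance, load_catalog

catalog = load_catalog()
panel = catalog.panel

print("Su(var) phyletic profiles (species columns At..Cp):")
for entry in catalog.family_entries("Su(var)"):
    print(f"  {str(entry.label):10s} {str(entry.backbone):40s}"
          f" {entry.presence_string()}")

print()
for domain, family in [("PostSET", "Ash"), ("SRA", "Su(var)"),
                       ("PWWP", "Trx"), ("WIYLD", "Su(var)")]:
    fa = earliest_appearance(list(catalog), domain, family, panel=panel)
    print(f"{domain:8s} in {family:8s} first appears in {fa.species:3s}"
          f" ({panel[fa.species].name}, {fa.lineage},"
          f" lineage rank {fa.lineage_rank}/16)")

print()
print("Rank 1 is the earliest-diverging lineage; e.g. the SRA domain on"
      " SET proteins is already present in chlorophyta, not first in"
      " bryophyta.")
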
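"""Parse sphingolipid shorthand names and classify their structure.

Both the shorthand-2020 dialect and the legacy d/t dialect are accepted;
everything downstream (subclass totals, base/acyl decomposition, set
enrichment) is driven by the three structural axes shown here.
"""

from sphingoquant import classify_acyl, classify_spb, parse_species_name, subclass_label

for name in [
    "HexCer 18:1;O2/24:0",   # canonical glucosyl/galactosylceramide
    "Cer 18:0;O2/16:0",      # saturated base -> dihydroceramide
    "Cer d18:1/h24:0",       # legacy dialect, hydroxylated acyl
    "GM3 18:2;O2/24:1",      # ganglioside with a sphingadiene base
]:
    sp = parse_species_name(name)
    print(
        f"{name:24s} -> {sp.name:24s} subclass={subclass_label(sp):8s} "
        f"base={classify_spb(sp, merge_sph_spd=True):10s} acyl={classify_acyl(sp)}"
    )

# The labels partition the panel: every species has exactly one subclass,
# one sphingoid-base class and one acyl class, which is what makes the
# subclass / base / chain-length aggregations well defined.
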
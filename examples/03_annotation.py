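"""Annotate each variant: phospho sites, sarcomeric home, interaction class.

The annotations are exon-composition rules: the exon-5 segment carries
S61, exon 10 carries S206, and the (exon31, exon32) tail determines both
localization (M-band vs A-band C-zone) and light-meromyosin binding.
"""

from smybpc import (
    annotate_phospho,
    interaction_profile,
    load_catalog,
    predict_localization,
)

catalog = load_catalog()
print(f"{'variant':8} {'phospho sites':22} {'localization':12} {'NH2 class':20} LMM")
for rec in catalog:
    phos = annotate_phospho(rec)
    loc = predict_localization(rec)
    inter = interaction_profile(rec)
    sites = ",".join(sorted(phos.site_names)) or "-"
    print(
        f"{rec.id:8} {sites:22} {loc.value:12} {inter.nterm_class:20} "
        f"{inter.lmm_binding}"
    )

# Expect: S61 only in h-v1/h-v2 (the only variants keeping exon 5), S206
# missing only in h-v8 (exon 10 skipped), and no Pro/Ala sites in h-v012
# (internal start in exon 7). 'unknown' is reported, never imputed.
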
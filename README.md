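# smybpc

Slow myosin binding protein-C (sMyBP-C) is not one protein: the single
*MYBPC1* gene produces a family of splice variants — 14 cataloged in human,
2 full-length in mouse — that differ by short in-frame segments in the
Pro/Ala-rich NH2-terminus (exons 2–5), the M-motif (exon 10), FnIII domain
C7 (exon 23), and the extreme COOH-terminus (exons 31–33). Because the
variants differ by only a few kilodaltons and no variant-specific antibodies
exist, single-fiber western blots resolve *molecular-weight groups* of
variants rather than individual proteoforms.

`smybpc` is a library for working with this family quantitatively. It is
aimed at muscle biologists and bioinformaticians who need to reason about
sMyBP-C splice logic, predict variant masses, and interpret single-fiber
band profiles. It provides:

* **Variant catalog** (`smybpc.catalog`) — the machine-readable exon
  architecture and inclusion matrix of all 16 variants, with the splice
  grammar enforced (frame-preserving cassettes; the exon 32 / exon 33
  stop-codon rule; internal-start handling for h-v012).
* **Proteoform annotation** (`smybpc.annotation`) — rule-based
  phosphorylation-site complements (PKA/PKC sites S61, T64, S85, S206 in
  human numbering), sarcomeric localization (A-band C-zone vs M-band
  periphery) and actomyosin/LMM interaction classes.
* **Mass model** (`smybpc.mass`) — an anchored delta-mass predictor,

      MW(v) = MW(h-v9) + Δaa(v, h-v9) · m̄,   m̄ = 0.110 kDa/residue,

  rounded to 0.5 kDa, plus the six MW groups (131–131.5 down to 115.5 kDa)
  used to interpret bands.
* **Gel pipeline** (`smybpc.gel`) — semilog SDS-PAGE sizing
  (log₁₀ MW = a + b·Rf fitted over a ladder lane by OLS) and
  nearest-center group assignment with explicit ambiguity flags.
* **Fiber profiling** (`smybpc.fibers`) — pattern tallies, expression
  multiplicity, per-group occurrence and myosin-isoform association across
  single fibers.
* **Synthetic data** (`smybpc.synth`) — deterministic fixtures rebuilding
  the published 48-fiber soleus / 41-fiber FDB datasets from their printed
  pattern frequencies (via exact integer apportionment), and seeded gel
  simulations with Gaussian migration noise and full ground truth.

## Worked example

```python
from smybpc import (fdb_preset, generate_fixture, recover_fibers,
                    tally_patterns, group_occurrence)

fixture = generate_fixture(fdb_preset())          # 41 fast-twitch fibers
fibers, _ = recover_fibers(fixture.bands, fixture.ladder, "FDB")
for t in tally_patterns(fibers):
    print(t.pattern_key, t.count, f"{t.percent}%")
print(group_occurrence(fibers)[6])
```

prints

```
(1,) 16 39%
(2,) 13 32%
(3,) 7 17%
(4,) 3 7%
(5,) 2 5%
0.0
```

Every FDB fiber carries exactly one MW group; group 1 (v1/v5/v202) is the
most common at 39%, and group 6 (the short v012 variant) never appears in
fast-twitch fibers — in contrast to slow-twitch soleus fibers, where 73%
of fibers co-express two groups and the group 1 + group 6 pairing alone
accounts for 40% of fibers (run `python examples/05_fiber_profiles.py`).

The `examples/` directory holds one short narrative script per capability
(catalog overview, mass prediction, annotation, gel sizing, fiber profiling,
simulation recovery). A thin CLI mirrors the same operations:
`smybpc summary`, `smybpc annotate --variant h-v8`, `smybpc predict-mw
--variant h-v013`, `smybpc groups`, `smybpc assign`, `smybpc profile`,
`smybpc simulate`.

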
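"""Template filtering, greedy selection and coverage accounting.

Hits are kept when significant (HMM channel: probability >95%, span >30,
identity >20%; high-identity channel: identity >70%), then selected
greedily by identical-residue count; an overlapping template is kept only
if it contributes at least 30 residues not yet covered.
"""

from collections import defaultdict

from centrokit import (
    SyntheticSpec,
    TemplateHit,
    coverage_summary,
    filter_hits,
    greedy_select,
    sample_protein_set,
    sample_template_hits,
)

# hand-traced single-query example
hits = [
    TemplateHit("P1", 1, 100, "A", identity=0.50),    # 50 identical
    TemplateHit("P1", 80, 200, "B", identity=0.40),   # 48 identical
    TemplateHit("P1", 90, 130, "C", identity=0.90),   # 37 identical
]
accepted = greedy_select(hits)
print("accepted templates:", [h.template_id for h in accepted])
print("B overlaps A but adds residues 101-200 (>=30 new); C adds none.\n")

# cohort-scale accounting on synthetic ground truth
spec = SyntheticSpec(n_proteins=300, seed=2)
records, track_set, _ = sample_protein_set(spec)
cohort_hits, ledger = sample_template_hits(spec, records, track_set)
by_query = defaultdict(list)
for h in filter_hits(cohort_hits):
    by_query[h.query_id].append(h)
selected = {q: greedy_select(hs) for q, hs in by_query.items()}
cs = coverage_summary(selected, {r.id: len(r) for r in records}, track_set)

print(f"set-level modeled fraction: {cs.set_modeled_fraction:.3f} "
      f"(generator design 0.276)")
print(f"modeled fraction in ordered regions:    "
      f"{cs.crosstab['p_modeled_given_ordered']:.3f}")
print(f"modeled fraction in disordered/coil:    "
      f"{cs.crosstab['p_modeled_given_disorder_or_coil']:.3f}")
print(f"unmodeled residues that are dis./coil:  "
      f"{cs.crosstab['p_disorder_or_coil_given_unmodeled']:.3f}")
print(f"fragments <30% identity: {cs.n_fragments_below_30}, "
      f">90%: {cs.n_fragments_above_90} (bimodal identity distribution)")
print("Lack of template coverage concentrates almost entirely in "
      "disordered and coiled-coil regions.")
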
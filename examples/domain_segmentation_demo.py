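"""Partition a protein into domains/stretches and call globular regions.

Priority: SMART domain > coil stretch (>20 residues) > disorder stretch
(>20 residues) > residual.  Residual regions longer than 40 residues with
an alignment Z-score above 3 and under 30% disordered-or-coil residues
are called putative globular domains.
"""

from centrokit import AnnotationTrack, Interval, call_globular, \
    identity_filter, partition_sequence

L = 500
smart = [Interval("DEMO", 10, 60, "smart_domain",
                  {"domain_name": "WD40", "significant": True})]
coil = AnnotationTrack("DEMO", "coil",
                       [130 <= i + 1 <= 200 for i in range(L)])
disorder = AnnotationTrack("DEMO", "disorder",
                           [70 <= i + 1 <= 120 for i in range(L)])

partition = partition_sequence(L, "DEMO", smart, coil, disorder)
print("partition:")
for iv in partition:
    print(f"  [{iv.start:3d},{iv.end:3d}] {iv.type}")

# the long C-terminal residual region has a confident structural alignment
alignments = {("DEMO", 201, 500): {"z_score": 4.2, "match_length": 280}}
calls = call_globular(partition, alignments, disorder, coil)
calls = identity_filter(calls, {("DEMO", 201, 500): 0.28})

print("\ncalls:")
for c in calls:
    print(f"  [{c.interval.start:3d},{c.interval.end:3d}] "
          f"{c.interval.type:16s} -> {c.verdict} ({c.rejection_reason})")
print("\nThe SMART domain passes condition 1 (significant, >=30 residues); "
      "the residual region passes condition 2 (Z>3, ordered) and survives "
      "the 40% identity filter, so both are candidates for expression "
      "constructs.")
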
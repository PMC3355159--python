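"""Aggregate a set of ranked lists into one optimal list by Borda count.

Features are ordered by how many lists extract them, ties by mean
position; on complete lists this is the classical Borda count.
"""

from canberrank import FeatureUniverse, ListSet, RankedList, borda_list

universe = FeatureUniverse(("TP53", "ERG", "AR", "PTEN", "MYC"))
lists = ListSet(
    universe,
    (
        RankedList(("ERG", "AR", "TP53")),
        RankedList(("ERG", "TP53")),
        RankedList(("AR", "ERG", "PTEN")),
    ),
)

result = borda_list(lists, include_unextracted=True)
print("feature  extractions  mean_position")
for entry in result.entries:
    pos = "-" if entry.mean_position is None else f"{entry.mean_position:.2f}"
    print(f"{entry.feature:8s} {entry.extractions:11d}  {pos}")
print("optimal list:", " > ".join(result.ranking))

# ERG leads: extracted by all three lists at mean position 1.33.  MYC is
# extracted by no list and is appended last only because of
# include_unextracted=True.
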
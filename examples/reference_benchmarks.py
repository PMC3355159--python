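"""Reference behaviour of the measures as the universe grows.

Left: normalized Core/Complete for three length-10 shared-support pairs
(identical, one random draw, maximally distant) at universe sizes 100 to
100000 — the Complete measure of even *identical* partial lists climbs
toward 1 as unselected features dominate, while Core stays support-sized.
Right: mean/variance over 10 replicates of the stability indicator for
sets of random complete lists — always near 1, by construction of the
normalizer E(p).
"""

from canberrank import partial_pair_table, stability_replicates

print("p       pair         core      complete")
for c in (2, 3, 4, 5):
    rows = partial_pair_table(10**c, 10, seed=42 + c)
    for name in ("identical", "random", "max_distant"):
        row = rows[name]
        print(f"{10**c:<7d} {name:12s} {row['core']:.6f}  {row['complete']:.6f}")

print()
print("n   p      mean      variance   (normalized stability indicator)")
for n, p in ((5, 10), (10, 10), (10, 1000)):
    mean, var = stability_replicates(n, p, replicates=10, seed=42)
    print(f"{n:<3d} {p:<6d} {mean:.6f}  {var:.7f}")
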
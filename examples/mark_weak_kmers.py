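"""Identify weak canonical k-mers in a small sequence with every algorithm.

A k-mer of a set K is *weak* if another member of K is one substitution
away (up to reverse complement).  All five algorithms — the two naive
baselines, the FourWay recursion, its pairwise hybrid, and the Quarter
bucketing method — must produce the identical weak/strong partition.
"""

import tempfile

import strongmark as sm

FASTA = """>toy
ACGGTCAGGTTACGGTCAGGATCCAGTTACGGTCAGCT
"""

with tempfile.NamedTemporaryFile("w", suffix=".fa", delete=False) as fh:
    fh.write(FASTA)
    path = fh.name

k = 9
kset = sm.count_canonical_kmers(path, k)
print(f"{len(kset)} distinct canonical {k}-mers counted (counts saturate at 2)")

for algo in ("pairwise", "neighborhood", "fourway", "fourway-pairwise", "quarter"):
    res = sm.run_marking(kset, algorithm=algo)
    print(f"{algo:>18}: {len(res.weak)} weak, {len(res.strong)} strong")

res = sm.run_marking(kset)
print("\nweak canonical k-mers (have a distance-1 partner in the set):")
for c in res.weak:
    print("  ", sm.decode(int(c), k))
print(f"weak fraction: {res.weak_fraction:.3f}")
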
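"""Extremal synthetic datasets: arrays that are all-weak or all-strong.

The all-weak generator pairs every random k-mer with a one-substitution
neighbor; the all-strong generator removes every weak k-mer from an
oversampled random array.  The marking pipeline must report weak
fractions of exactly 1.0 and 0.0 respectively — a strong end-to-end check
scaled to any size.
"""

from strongmark.driver import mark_expanded
from strongmark.synthetic import SyntheticSpec, gen_all_strong, gen_all_weak

for k in (13, 21, 31):
    aw = gen_all_weak(SyntheticSpec(n=10_000, k=k, seed=1, mode="all_weak"))
    st = gen_all_strong(SyntheticSpec(n=10_000, k=k, seed=2, mode="all_strong"))
    f_weak = mark_expanded(aw, algorithm="fourway-pairwise").weak_fraction
    f_strong = mark_expanded(st, algorithm="quarter").weak_fraction
    print(f"k={k:2d}: all-weak array -> weak fraction {f_weak:.1f}; "
          f"all-strong array -> weak fraction {f_strong:.1f}")
print("\n1.0 / 0.0 confirm both the generators' contracts and the markers.")
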
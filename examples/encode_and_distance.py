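"""Canonical k-mer codes and bit-parallel Hamming distances.

A k-mer is stored as a base-4 integer (A=0, C=1, G=2, T=3, leftmost
character most significant); a k-mer and its reverse complement share one
canonical code, and distances are taken over the best orientation.
"""

import strongmark as sm

code = sm.encode("TACG")
rc = sm.rc_code(code, 4)
print(f"enc(TACG) = {code}  (base-4 digits 3,0,1,2)")
print(f"enc(rc(TACG)) = enc(CGTA) = {rc}")
print(f"cc(TACG) = cc(CGTA) = max({code}, {rc}) = {sm.canonical_code(code, 4)}")

x, y = sm.encode("AAAA"), sm.encode("ATTT")
print(f"\nplain Hamming distance d(AAAA, ATTT) = {sm.hamming(x, y, 4)}")
print(f"canonical Hamming distance H(AAAA, ATTT) = {sm.canonical_hamming(x, y, 4)}")
print("-> as double-stranded molecules the two k-mers are a single substitution")
print("   apart: rc(ATTT) = AAAT differs from AAAA at one position only.")
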
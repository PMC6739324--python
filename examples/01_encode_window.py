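"""Encode a single DNA window with each feature scheme.

Prints the nucleic-shift-density trace of C along CAGCTG — the canonical
worked example of the prefix-density definition — then the sizes of each
feature block for a 41-nt window.
"""

import sixma as sx

print("Nucleic shift density of 'C' along CAGCTG:")
print("  ", [round(sx.nsd_at("CAGCTG", "C", i), 4) for i in range(1, 7)])
print("  (at each position: count of C in the prefix / prefix length)\n")

window = "GTATCCTCGATGCTCCACCGATCCAGGCATGAGTGTAGCAG"  # a 41-nt window
assert len(window) == 41

kmer = sx.encode_kmer(window, ks=[2, 3, 4])
ksnpf = sx.encode_ksnpf(window, ks=[1, 2, 3, 4])
nsd = sx.encode_nsd(window)
binary = sx.encode_binary(window)
motif = sx.encode_motifs(window, [sx.default_planted_motif()])

print(f"k-mer frequencies (k=2,3,4):        {len(kmer)} features")
print(f"k-spaced pair frequencies (k=1..4): {len(ksnpf)} features")
print(f"nucleic shift density:              {len(nsd)} features")
print(f"binary 3-bit code:                  {len(binary)} features")
print(f"motif log-odds scores:              {len(motif)} feature(s)")
print("\nEach k-mer / pair block sums to 1 (a distribution over patterns):")
print(f"  sum of 2-mer block = {kmer[:16].sum():.6f}")
print(f"\nBest log-odds hit of the ACCGATCSA matrix: {motif.iloc[0]:.2f} bits")
print("(positive = the window contains a better-than-background motif match)")
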
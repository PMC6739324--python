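"""Parse a MEME minimal-format motif file and score windows against it.

Motifs with E-value below 0.05 are kept (the usual significance cut for
enriched motifs); each kept matrix contributes one max-over-windows log-odds
feature per sequence.
"""

from pathlib import Path

import sixma as sx

meme_text = """\
MEME version 4

ALPHABET= ACGT

Background letter frequencies
A 0.25 C 0.25 G 0.25 T 0.25

MOTIF ACCGATCSA
letter-probability matrix: alength= 4 w= 9 nsites= 20 E= 2.9e-2
0.91 0.03 0.03 0.03
0.03 0.91 0.03 0.03
0.03 0.91 0.03 0.03
0.03 0.03 0.91 0.03
0.91 0.03 0.03 0.03
0.03 0.03 0.03 0.91
0.03 0.91 0.03 0.03
0.05 0.45 0.45 0.05
0.91 0.03 0.03 0.03

MOTIF NOISE
letter-probability matrix: alength= 4 w= 4 nsites= 10 E= 0.8
0.25 0.25 0.25 0.25
0.25 0.25 0.25 0.25
0.25 0.25 0.25 0.25
0.25 0.25 0.25 0.25
"""

path = Path("scratch") / "example_motifs.meme"
path.parent.mkdir(exist_ok=True)
path.write_text(meme_text)

motifs = sx.read_meme_motifs(path)
print(f"parsed {len(motifs)} motifs: "
      + ", ".join(f"{m.name} (w={m.width}, E={m.evalue:g})" for m in motifs))

kept = sx.filter_motifs_by_evalue(motifs, threshold=0.05)
print(f"kept {len(kept)} motif(s) with E < 0.05: {[m.name for m in kept]}")

with_hit = "TTTTTTTTTTTTTTTTACCGATCCATTTTTTTTTTTTTTTT"
without = "TTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTT"
for label, seq in [("window with ACCGATCCA", with_hit), ("poly-T window", without)]:
    score = sx.score_motif(seq, kept[0])
    print(f"{label}: best log-odds = {score:+.2f} bits")
print("(a strongly positive score marks a better-than-background motif match;"
      " a negative score means no window resembles the motif)")
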
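"""Scan a PWM over a sequence FIMO-style and print the hits.

Scores are log2 likelihood ratios against a uniform background; p-values
come from the exact PWM score distribution. Both strands are scanned and
windows containing N are skipped.
"""

import numpy as np

from epmotif import PWM, scan
from epmotif.genome_io import SequenceRecord, reverse_complement

consensus = "TGACGTGG"
probs = np.full((8, 4), 0.03)
for i, base in enumerate(consensus):
    probs[i, "ACGT".index(base)] = 0.91
pwm = PWM("demo", probs, pseudocount=0.0)

rng = np.random.default_rng(0)
background = "".join("ACGT"[i] for i in rng.integers(0, 4, 120))
seq = background[:40] + consensus + background[48:80] + reverse_complement(consensus) + background[88:]

for hit in scan(pwm, SequenceRecord("demo_seq", seq), p_threshold=1e-4):
    print(f"offset {hit.offset:3d}  strand {hit.strand}  "
          f"score {hit.score:5.2f} bits  p={hit.pvalue:.2e}")
# Expect the planted forward site at offset 40 on '+' and the
# reverse-complement site at offset 80 reported on the '-' strand.
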
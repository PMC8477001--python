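"""The internal-priming filter on a hand-built genomic neighbourhood.

Oligo(dT) priming on an A-rich genomic stretch mimics a poly(A) tail, so
reads ending just upstream of such a stretch are artifacts.  A read 3' end
is discarded when the 20 nt strictly downstream (transcript orientation)
contain more than 12 A's or a run of 8 consecutive A's.
"""

from apa3t import Genome, ReadEnd, filter_read_ends, is_internal_priming

#                 pos 30 |--- 15 A's: a priming trap ---|
seq = "C" * 30 + "A" * 15 + "CGTCGTACGT" * 5
genome = Genome({"chr1": seq})

for pos, label in [(29, "just upstream of the A stretch"),
                   (60, "in ordinary sequence")]:
    flagged = is_internal_priming(genome, "chr1", "+", pos)
    print(f"read end at {pos:>3} ({label}): "
          f"{'artifact, filtered' if flagged else 'kept'}")

reads = [ReadEnd("chr1", "+", 29, "s1")] * 40 + [
    ReadEnd("chr1", "+", 60, "s1")
] * 100
kept, removed = filter_read_ends(reads, genome)
print(f"\n{len(reads)} reads in, {len(kept)} kept, "
      f"{removed.get('s1', 0)} removed as internal priming")
print("The 40 reads piling up at the trap are exactly the ones removed.")
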
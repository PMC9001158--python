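"""PCR-duplicate removal for paired reads carrying a degenerate base region.

Reads from distinct template molecules can share an insert by chance (RAD
loci are a finite set of restriction fragments), so insert identity alone
over-removes.  The DBR — a random adapter tag ligated before PCR — breaks
that tie: two pairs are duplicates only if both mate prefixes AND the DBR
agree.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

from .io import ReadPair


@dataclasses.dataclass(frozen=True)
class DedupReport:
    n_input: int
    n_kept: int
    n_removed: int

    def __post_init__(self) -> None:
        if self.n_input != self.n_kept + self.n_removed:
            raise ValueError("n_input must equal n_kept + n_removed")

    @property
    def duplicate_rate(self) -> float:
        return self.n_removed / self.n_input if self.n_input else 0.0


def _mean_quality(pair: ReadPair) -> float:
    quals = pair.qual1 + pair.qual2
    if not quals:
        return 0.0
    return sum(ord(c) - 33 for c in quals) / len(quals)


def remove_pcr_duplicates(read_pairs: Iterable[ReadPair], key_length: int = 30
                          ) -> tuple[list[ReadPair], DedupReport]:
    """Keep one representative per (read1 prefix, read2 prefix, DBR) group.

    The representative is the pair with the highest mean base quality (ties
    broken by input order); output preserves input order.  A prefix of each
    mate (default 30 bases) is used rather than the full read, to be robust
    to 3' quality decay.
    """
    pairs: Sequence[ReadPair] = list(read_pairs)
    if not pairs:
        return [], DedupReport(0, 0, 0)
    dbr_len = len(pairs[0].dbr)
    best: dict[tuple[str, str, str], tuple[float, int]] = {}
    for idx, p in enumerate(pairs):
        if len(p.dbr) != dbr_len:
            raise ValueError(
                f"inconsistent DBR lengths: {dbr_len} vs {len(p.dbr)} (pair {p.id})")
        key = (p.read1_seq[:key_length], p.read2_seq[:key_length], p.dbr)
        q = _mean_quality(p)
        if key not in best or q > best[key][0]:
            best[key] = (q, idx)
    keep = sorted(idx for _, idx in best.values())
    kept = [pairs[i] for i in keep]
    return kept, DedupReport(len(pairs), len(kept), len(pairs) - len(kept))
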
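"""Pond-level breeding-system classification from observed genomotypes.

Which genomotypes co-occur in a pond constrains how the hybrids there can
reproduce: diploid LR hybrids alongside LL indicate the classic L-E system
(hybrids backcross with P. lessonae); LLR triploids alongside LL indicate
the modified L-E system (triploids depend on diploid hybrids); triploids
plus LR without any LL suggest an all-hybrid (E-E) population — but only as
a candidate, since the absence of LL from a finite sample may be a sampling
artifact.  RR individuals are flagged wherever they occur; they can be
invasive P. ridibundus-complex frogs or rare viable hybrid x hybrid
offspring, which pond composition alone cannot distinguish.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from typing import Iterable

import pandas as pd

from .diagnostic import E_UNKNOWN_PLOIDY, LL, LLR, LR, LRR, RR

L_E = "L_E"
MODIFIED_L_E = "MODIFIED_L_E"
E_E_CANDIDATE = "E_E_CANDIDATE"
UNDETERMINED_SYSTEM = "UNDETERMINED"
RR_PRESENT = "RR_PRESENT"


@dataclasses.dataclass
class PondSummary:
    pond_id: str
    counts: dict[str, int]
    system: str
    notes: list[str]


def classify_pond(pond_id: str, labels: Iterable[str]) -> PondSummary:
    """Breeding-system call for one pond from its individuals' genomotypes.

    Rules, applied in order: triploids (LLR or LRR) with LR but no LL ->
    E_E_CANDIDATE; LLR together with LL -> MODIFIED_L_E; LL together with
    LR -> L_E; a single observed genomotype -> UNDETERMINED ("single-taxon
    sample").  Hybrids of unknown ploidy count as LR-or-LLR presence for
    the plain L-E rule only — they cannot establish triploidy.  RR presence
    adds an RR_PRESENT note whatever the system.
    """
    labels = list(labels)
    if not labels:
        raise ValueError(f"pond {pond_id!r} has no genomotype calls")
    counts = dict(Counter(labels))
    present = set(counts)
    notes: list[str] = []
    lr_like = LR in present or E_UNKNOWN_PLOIDY in present
    if (LLR in present or LRR in present) and LL not in present and LR in present:
        system = E_E_CANDIDATE
        notes.append("no LL sampled; absence may be a sampling artifact")
    elif LLR in present and LL in present:
        system = MODIFIED_L_E
    elif LL in present and lr_like:
        system = L_E
    elif len(present) == 1:
        system = UNDETERMINED_SYSTEM
        notes.append("single-taxon sample")
    else:
        system = UNDETERMINED_SYSTEM
        notes.append("no breeding-system rule matched")
    if RR in present:
        notes.append(RR_PRESENT)
    return PondSummary(pond_id=pond_id, counts=counts, system=system, notes=notes)


def summarize_ponds(calls: pd.DataFrame) -> pd.DataFrame:
    """Pond summaries from a calls table with ``pond`` and ``label`` columns."""
    rows = []
    for pond, sub in calls.groupby("pond", sort=False):
        summary = classify_pond(str(pond), list(sub["label"]))
        row = {"pond": summary.pond_id, "system": summary.system,
               "notes": ";".join(summary.notes)}
        for g in (LL, LR, LLR, LRR, RR, E_UNKNOWN_PLOIDY):
            row[f"n_{g}"] = summary.counts.get(g, 0)
        rows.append(row)
    return pd.DataFrame(rows)
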
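"""Single-locus marker calls and method-concordance statistics.

The nuclear MND1 marker distinguishes the L and R genomes by two nucleotide
substitutions within a 33-bp fragment: pure P. lessonae reads show the L
state at both positions, individuals with an RR genotype the R state, and
the hybrid P. kl. esculentus — carrying one genome of each — shows IUPAC
ambiguity codes at both positions in Sanger-style sequence.  The
mitochondrial ND1 fragment assigns a maternal haplogroup by nearest
reference sequence (Hamming distance).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import edlib
import pandas as pd

LESSONAE = "LESSONAE"
ESCULENTUS = "ESCULENTUS"
RR_GENOTYPE = "RR_GENOTYPE"
UNIDENTIFIED = "UNIDENTIFIED"

MARKER_LABELS = [LESSONAE, ESCULENTUS, RR_GENOTYPE, UNIDENTIFIED]

IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}

AMBIGUITY_CODE = {frozenset(v): k for k, v in IUPAC_SETS.items() if len(v) == 2}


class MarkerAlignmentError(ValueError):
    """Query sequence cannot be aligned to the marker template."""


@dataclasses.dataclass(frozen=True)
class Mnd1Templates:
    """The two MND1 allele templates; they must differ at exactly 2 sites."""

    l_seq: str
    r_seq: str

    def __post_init__(self) -> None:
        if len(self.l_seq) != len(self.r_seq):
            raise ValueError("MND1 allele templates differ in length")
        if len(self.diagnostic_positions) != 2:
            raise ValueError(
                f"MND1 templates must differ at exactly 2 positions, "
                f"found {len(self.diagnostic_positions)}")

    @property
    def diagnostic_positions(self) -> tuple[int, ...]:
        return tuple(i for i, (a, b) in enumerate(zip(self.l_seq, self.r_seq))
                     if a != b)


#: Synthetic 33-bp MND1 allele templates used for testing and simulation;
#: the real diagnostic fragment is a configurable input.
def default_mnd1_templates() -> Mnd1Templates:
    l_seq = "ATGGCTTACCAGTCGATCTGAACGTTCAGGTCA"
    # R allele: substitutions at positions 10 (A->T) and 22 (C->G)
    r_seq = l_seq[:10] + "T" + l_seq[11:22] + "G" + l_seq[23:]
    return Mnd1Templates(l_seq=l_seq, r_seq=r_seq)


def call_mnd1(sequence: str, templates: Mnd1Templates | None = None,
              max_edit_distance: int = 8) -> str:
    """Species call from one MND1 fragment sequence.

    Both diagnostic positions in the L state -> LESSONAE; both in the R
    state -> RR_GENOTYPE; both carrying the two-base IUPAC code for the
    L/R states -> ESCULENTUS (one genome of each parent); anything else
    (one position ambiguous, discordant states, unreadable bases) ->
    UNIDENTIFIED.  Note the method's inherent blind spot: an individual
    with an RR genotype that is heterozygous by descent at MND1 is called
    ESCULENTUS.
    """
    if templates is None:
        templates = default_mnd1_templates()
    seq = sequence.upper()
    dist = min(
        edlib.align(seq, templates.l_seq, task="distance")["editDistance"],
        edlib.align(seq, templates.r_seq, task="distance")["editDistance"],
    )
    if dist > max_edit_distance or len(seq) != len(templates.l_seq):
        raise MarkerAlignmentError(
            f"sequence (length {len(seq)}, edit distance {dist}) is not "
            f"alignable to the {len(templates.l_seq)}-bp MND1 template")
    states = []
    for pos in templates.diagnostic_positions:
        base, l_base, r_base = seq[pos], templates.l_seq[pos], templates.r_seq[pos]
        if base == l_base:
            states.append("L")
        elif base == r_base:
            states.append("R")
        elif IUPAC_SETS.get(base) == {l_base, r_base}:
            states.append("LR")
        else:
            states.append("?")
    if states == ["L", "L"]:
        return LESSONAE
    if states == ["R", "R"]:
        return RR_GENOTYPE
    if states == ["LR", "LR"]:
        return ESCULENTUS
    return UNIDENTIFIED


@dataclasses.dataclass(frozen=True)
class HaplogroupCall:
    haplogroup: str
    distance: int
    tie: bool = False


def assign_nd1_haplogroup(sequence: str, references: Mapping[str, str]) -> HaplogroupCall:
    """Nearest mitochondrial reference by Hamming distance.

    ``references`` maps haplogroup names (e.g. lessonae / ridibundus /
    bedriagae) to aligned sequences of the same length as the query.  A tie
    for the minimum distance returns UNIDENTIFIED with the tie flag set.
    """
    if not references:
        raise ValueError("no reference sequences supplied")
    seq = sequence.upper()
    dists: dict[str, int] = {}
    for name, ref in references.items():
        if len(ref) != len(seq):
            raise ValueError(
                f"reference {name!r} length {len(ref)} != query length {len(seq)}")
        dists[name] = sum(a != b for a, b in zip(seq, ref.upper()))
    best = min(dists.values())
    winners = [n for n, d in dists.items() if d == best]
    if len(winners) > 1:
        return HaplogroupCall(haplogroup=UNIDENTIFIED, distance=best, tie=True)
    return HaplogroupCall(haplogroup=winners[0], distance=best)


# ----------------------------------------------------------- concordance

def _normalise(label: object) -> str:
    if label is None or label in ("?", "", "nan"):
        return UNIDENTIFIED
    return str(label)


def concordance(calls_a: Mapping[str, str], calls_b: Mapping[str, str]
                ) -> tuple[pd.DataFrame, int, int, float]:
    """Cross-tabulate two per-individual call maps and score their agreement.

    Returns ``(confusion_table, n_matched, n_mismatched, rate)`` where the
    confusion table has method-A labels as rows and method-B labels as
    columns (UNIDENTIFIED included).  Matches and mismatches are counted
    only over individuals identified by BOTH methods; ``rate`` is
    n_matched / (n_matched + n_mismatched).
    """
    shared = [i for i in calls_a if i in calls_b]
    if not shared:
        raise ValueError("call maps share no individual ids")
    a = [_normalise(calls_a[i]) for i in shared]
    b = [_normalise(calls_b[i]) for i in shared]
    labels = list(MARKER_LABELS) + sorted(set(a) | set(b) - set(MARKER_LABELS))
    labels = list(dict.fromkeys(l for l in labels if l in set(a) | set(b)))
    tab = pd.crosstab(pd.Series(a, name="method_a"), pd.Series(b, name="method_b"))
    tab = tab.reindex(index=labels, columns=labels, fill_value=0)
    n_matched = int(sum(tab.loc[l, l] for l in labels if l != UNIDENTIFIED))
    n_mismatched = int(
        sum(tab.loc[r, c] for r in labels for c in labels
            if r != c and UNIDENTIFIED not in (r, c)))
    denom = n_matched + n_mismatched
    if denom == 0:
        raise ValueError("no individuals identified by both methods")
    return tab, n_matched, n_mismatched, n_matched / denom


def expand_counts_to_calls(counts: Mapping[tuple[str, str], int]
                           ) -> tuple[dict[str, str], dict[str, str]]:
    """Turn a printed confusion table into two synthetic call maps.

    ``counts`` maps (method_a_label, method_b_label) -> individual count;
    the returned maps reproduce exactly that confusion table when fed to
    :func:`concordance`.
    """
    calls_a: dict[str, str] = {}
    calls_b: dict[str, str] = {}
    k = 0
    for (la, lb), n in counts.items():
        for _ in range(int(n)):
            ind = f"ind{k:04d}"
            calls_a[ind] = la
            calls_b[ind] = lb
            k += 1
    return calls_a, calls_b
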
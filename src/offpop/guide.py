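"""Core sequence types and bulge-aware alignment of candidates to a guide.

Alignment model: a candidate is 21-25 nt of genomic sequence in guide
orientation, the last three bases being the PAM slot.  The 20-nt spacer is
aligned to the candidate minus its PAM with a banded dynamic program that
minimizes, lexicographically, (indel count, mismatch count).  Ties between
equal-cost gap placements are resolved toward the PAM-proximal (3') end,
which is the placement convention pinned down by the published per-site
scores this package is validated against.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio.Seq import reverse_complement
from Bio.SeqUtils import gc_fraction

from .errors import ParameterError, UnsupportedLengthError, ValidationError

SPACER_LEN = 20
PAM_LEN = 3
MIN_CANDIDATE_LEN = 21
MAX_CANDIDATE_LEN = 25
BAND_WIDTH = 2

GAP = "-"
_SEQ_RE = re.compile(r"^[ACGT]+$")
# lowercase letters mark predictor-declared inserted bases (the unified-TSV
# equivalent of italics in predictor reports); '-' marks deletions
_OBS_RE = re.compile(r"^[ACGTNacgtn-]+$")

# IUPAC nucleotide codes -> the set of bases they match.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}

MATCH = "match"
MISMATCH = "mismatch"
INSERTION = "insertion_in_target"
DELETION = "deletion_in_target"


def matches_iupac(seq: str, pattern: str) -> bool:
    """True iff ``seq`` matches the IUPAC ``pattern`` of equal length."""
    if len(seq) != len(pattern):
        return False
    try:
        return all(b in IUPAC[p] for b, p in zip(seq.upper(), pattern.upper()))
    except KeyError as exc:  # pragma: no cover - config error
        raise ParameterError(f"invalid IUPAC code in pattern {pattern!r}") from exc


@dataclass(frozen=True)
class GuideRNA:
    """A 20-nt spacer plus the IUPAC PAM pattern it requires."""

    name: str
    spacer: str
    pam_pattern: str = "NGG"

    def __post_init__(self):
        if len(self.spacer) != SPACER_LEN or not _SEQ_RE.match(self.spacer):
            raise ValidationError(
                f"spacer must be {SPACER_LEN} nt of A/C/G/T, got {self.spacer!r}"
            )
        if len(self.pam_pattern) != PAM_LEN or any(
            c not in IUPAC for c in self.pam_pattern
        ):
            raise ValidationError(f"PAM pattern must be an IUPAC trinucleotide")

    @property
    def gc_fraction(self) -> float:
        return gc_fraction(self.spacer)

    @property
    def gc_percent(self) -> int:
        return round(self.gc_fraction * 100)


@dataclass
class CandidateSite:
    """One putative off-target site.

    Coordinates are stored 0-based half-open; :meth:`locus` renders the
    1-based inclusive form used in reports.  ``observed_seq`` is in guide
    orientation and may carry ``-`` gap characters marking deletions.
    """

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    observed_seq: str
    sources: set = field(default_factory=set)
    annotation: str = "unknown"
    gene: Optional[str] = None
    flank5: str = ""
    flank3: str = ""

    def __post_init__(self):
        # case is preserved: lowercase marks predictor-declared insertions
        if self.strand not in "+-":
            raise ValidationError(f"{self.id}: strand must be + or -")
        if not _OBS_RE.match(self.observed_seq):
            raise ValidationError(
                f"{self.id}: invalid character in sequence {self.observed_seq!r}"
            )
        if self.end - self.start != len(self.ungapped):
            raise ValidationError(
                f"{self.id}: interval length {self.end - self.start} does not "
                f"match ungapped sequence length {len(self.ungapped)}"
            )

    @property
    def ungapped(self) -> str:
        return self.observed_seq.replace(GAP, "").upper()

    @property
    def genomic_seq(self) -> str:
        """Ungapped sequence on the genomic plus strand."""
        s = self.ungapped
        return s if self.strand == "+" else reverse_complement(s)

    def locus(self) -> str:
        return f"{self.chrom}:{self.start + 1}–{self.end}"


@dataclass(frozen=True)
class AlignmentColumn:
    guide_pos: Optional[int]  # 1..20, None for insertion columns
    guide_base: str           # '-' for insertion columns
    target_base: str          # '-' for deletion columns
    op: str
    target_pos: Optional[int]  # 1-based within ungapped candidate; None for deletions


@dataclass
class GuideAlignment:
    """Per-column correspondence between a guide spacer and a candidate."""

    guide: GuideRNA
    columns: tuple
    pam_observed: str

    def __post_init__(self):
        if len(self.pam_observed) != PAM_LEN or GAP in self.pam_observed:
            raise ValidationError("PAM slot must be an ungapped trinucleotide")

    @property
    def mismatches(self) -> int:
        return sum(1 for c in self.columns if c.op == MISMATCH)

    @property
    def indels(self) -> int:
        return sum(1 for c in self.columns if c.op in (INSERTION, DELETION))

    @property
    def m_i(self) -> tuple:
        return (self.mismatches, self.indels)

    def reconstruct_target(self) -> str:
        """Gapped candidate sequence (spacer region + PAM)."""
        return "".join(c.target_base for c in self.columns) + self.pam_observed

    def reconstruct_guide(self) -> str:
        return "".join(
            c.guide_base for c in self.columns if c.op != INSERTION
        )

    def display_length(self) -> int:
        return len(self.columns) + PAM_LEN


def _validate_raw(seq: str, what: str) -> str:
    seq = seq.upper()
    if not _OBS_RE.match(seq) or GAP in seq:
        raise ValidationError(f"invalid character in {what} {seq!r}")
    return seq


def align(guide: GuideRNA, raw_seq: str) -> GuideAlignment:
    """Banded alignment of an ungapped 21-25 nt candidate to the guide.

    Minimizes (indels, mismatches) lexicographically within a band of
    +/-2 around the diagonal; among co-optimal alignments the one whose
    indel columns sit closest to the PAM is returned.
    """
    raw_seq = _validate_raw(raw_seq, "candidate")
    if not MIN_CANDIDATE_LEN <= len(raw_seq) <= MAX_CANDIDATE_LEN:
        raise UnsupportedLengthError(
            f"candidate length {len(raw_seq)} outside "
            f"[{MIN_CANDIDATE_LEN},{MAX_CANDIDATE_LEN}]"
        )
    proto, pam = raw_seq[:-PAM_LEN], raw_seq[-PAM_LEN:]
    g = guide.spacer
    n = len(proto)
    big = (10**6, 10**6)
    # dp[i][j]: minimal (indels, mismatches) aligning g[:i] to proto[:j]
    dp = [[big] * (n + 1) for _ in range(SPACER_LEN + 1)]
    dp[0][0] = (0, 0)
    for i in range(SPACER_LEN + 1):
        for j in range(n + 1):
            if abs(i - j) > BAND_WIDTH or (i == 0 and j == 0):
                continue
            best = big
            if i > 0 and j > 0 and dp[i - 1][j - 1] != big:
                ind, mm = dp[i - 1][j - 1]
                cand = (ind, mm + (0 if g[i - 1] == proto[j - 1] else 1))
                best = min(best, cand)
            if i > 0 and abs(i - 1 - j) <= BAND_WIDTH and dp[i - 1][j] != big:
                ind, mm = dp[i - 1][j]
                best = min(best, (ind + 1, mm))
            if j > 0 and abs(i - (j - 1)) <= BAND_WIDTH and dp[i][j - 1] != big:
                ind, mm = dp[i][j - 1]
                best = min(best, (ind + 1, mm))
            dp[i][j] = best
    if dp[SPACER_LEN][n] == big:  # pragma: no cover - band always suffices here
        raise UnsupportedLengthError("alignment fell outside the band")

    # Traceback, preferring gap moves while walking from the 3' end so that
    # co-optimal indels land PAM-proximal.
    cols = []
    i, j = SPACER_LEN, n
    while i > 0 or j > 0:
        here = dp[i][j]
        if j > 0 and abs(i - (j - 1)) <= BAND_WIDTH and dp[i][j - 1] != big \
                and (dp[i][j - 1][0] + 1, dp[i][j - 1][1]) == here:
            cols.append(AlignmentColumn(None, GAP, proto[j - 1], INSERTION, j))
            j -= 1
        elif i > 0 and abs(i - 1 - j) <= BAND_WIDTH and dp[i - 1][j] != big \
                and (dp[i - 1][j][0] + 1, dp[i - 1][j][1]) == here:
            cols.append(AlignmentColumn(i, g[i - 1], GAP, DELETION, None))
            i -= 1
        else:
            op = MATCH if g[i - 1] == proto[j - 1] else MISMATCH
            cols.append(AlignmentColumn(i, g[i - 1], proto[j - 1], op, j))
            i -= 1
            j -= 1
    cols.reverse()
    return GuideAlignment(guide=guide, columns=tuple(cols), pam_observed=pam)


def parse_gapped(guide: GuideRNA, gapped_seq: str) -> GuideAlignment:
    """Build an alignment from a predictor-style gapped sequence.

    ``-`` characters mark deletions in the target; lowercase letters mark
    predictor-declared inserted bases (the plain-text stand-in for the
    italics used in predictor reports).  Sequences longer than 23 nt
    once gaps are removed that carry no insertion markup have their
    insertion placement re-derived with :func:`align`.
    """
    if not _OBS_RE.match(gapped_seq):
        raise ValidationError(f"invalid character in {gapped_seq!r}")
    if not MIN_CANDIDATE_LEN <= len(gapped_seq) <= MAX_CANDIDATE_LEN:
        raise UnsupportedLengthError(
            f"gapped length {len(gapped_seq)} outside "
            f"[{MIN_CANDIDATE_LEN},{MAX_CANDIDATE_LEN}]"
        )
    pam = gapped_seq[-PAM_LEN:]
    if GAP in pam:
        raise ValidationError("gap inside the PAM trinucleotide")
    if any(c.islower() for c in pam):
        raise ValidationError("insertion markup inside the PAM trinucleotide")
    spacer_part = gapped_seq[:-PAM_LEN]
    has_markup = any(c.islower() for c in spacer_part)
    if not has_markup:
        spacer_part = spacer_part.upper()
        if GAP not in spacer_part and len(spacer_part) != SPACER_LEN:
            # insertions present but unmarked: re-derive the placement
            return align(guide, gapped_seq.upper())
        if GAP in spacer_part and len(spacer_part) != SPACER_LEN:
            # gaps plus unmarked insertions mixed: re-derive
            return align(guide, gapped_seq.upper().replace(GAP, ""))
    cols = []
    gi = 0  # guide positions consumed
    tpos = 0  # target bases consumed
    for ch in spacer_part:
        if ch == GAP:
            gi += 1
            if gi > SPACER_LEN:
                raise ValidationError("gapped notation overruns the spacer")
            cols.append(AlignmentColumn(gi, guide.spacer[gi - 1], GAP,
                                        DELETION, None))
        elif ch.islower():
            tpos += 1
            cols.append(AlignmentColumn(None, GAP, ch.upper(), INSERTION, tpos))
        else:
            gi += 1
            tpos += 1
            if gi > SPACER_LEN:
                raise ValidationError("gapped notation overruns the spacer")
            gb = guide.spacer[gi - 1]
            op = MATCH if gb == ch else MISMATCH
            cols.append(AlignmentColumn(gi, gb, ch, op, tpos))
    if gi != SPACER_LEN:
        raise ValidationError(
            f"gapped notation consumes {gi} of {SPACER_LEN} guide positions"
        )
    return GuideAlignment(guide=guide, columns=tuple(cols), pam_observed=pam.upper())


def seed_conserved(a: GuideAlignment, seed_len: int = 5) -> bool:
    """True iff the ``seed_len`` PAM-proximal guide positions are exact.

    Any mismatch, deletion, or insertion column inside the seed span
    (including an insertion between the last spacer base and the PAM)
    breaks conservation.
    """
    if not 1 <= seed_len <= SPACER_LEN:
        raise ParameterError(f"seed_len {seed_len} outside [1,{SPACER_LEN}]")
    first_seed_pos = SPACER_LEN - seed_len + 1
    start_idx = None
    for idx, c in enumerate(a.columns):
        if c.guide_pos == first_seed_pos:
            start_idx = idx
            break
    if start_idx is None:  # seed position deleted entirely is impossible; guard
        return False
    return all(c.op == MATCH for c in a.columns[start_idx:])


def pam_check(a: GuideAlignment, pattern: str = "NGG") -> bool:
    """True iff the observed PAM trinucleotide matches the IUPAC pattern."""
    return matches_iupac(a.pam_observed, pattern)


def position_profile(alignments: Iterable[GuideAlignment]) -> pd.DataFrame:
    """Counts of mismatch/insertion/deletion per aligned display position.

    Positions are 1-based indices in the gapped candidate rendering
    (1..25); the PAM occupies the final three positions and never counts.
    """
    alignments = list(alignments)
    if not alignments:
        raise ParameterError("position_profile requires a nonempty list")
    table = pd.DataFrame(
        0,
        index=pd.RangeIndex(1, MAX_CANDIDATE_LEN + 1, name="position"),
        columns=["mismatch", "insertion", "deletion"],
    )
    opname = {MISMATCH: "mismatch", INSERTION: "insertion", DELETION: "deletion"}
    for a in alignments:
        for idx, c in enumerate(a.columns, start=1):
            if c.op in opname:
                table.loc[idx, opname[c.op]] += 1
    return table
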
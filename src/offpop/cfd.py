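"""Cutting-frequency-determination (CFD) scoring with indel support.

The bundled penalty resource holds per-position activity fractions for
mismatches (guide base vs observed target base), PAM trinucleotides, and
single-base insertions/deletions.  Scores are products of the relevant
activities:

* mismatch score  = prod(mismatch penalties) * PAM penalty
* indel score     = prod(indel penalties); undefined when the alignment
  has no indel columns
* final score     = mismatch score * indel score (or mismatch score alone)

Mismatch penalties for indel-bearing alignments are indexed by the guide
position of each mismatch column, which is equivalent to scoring the
candidate with inserted bases removed.  Insertion penalties are indexed
by the 1-based position the inserted base occupies in the ungapped
candidate and by the inserted base; deletion penalties by the deleted
guide position and guide base.  These conventions were fixed empirically
against published per-site scores for the bundled guide.

Thresholds (0.2 upper, 0.023 lower) are applied to unrounded values;
three-decimal rounding is display-only.
"""

from __future__ import annotations

import csv
import hashlib
import logging
from dataclasses import dataclass
from enum import Enum
from importlib import resources as importlib_resources
from pathlib import Path
from typing import Optional, Union

from .errors import PenaltyLookupError, ValidationError
from .guide import DELETION, INSERTION, MISMATCH, GuideAlignment, matches_iupac

log = logging.getLogger(__name__)

DEFAULT_RESOURCE = "cfd_penalties.tsv"
UPPER_THRESHOLD = 0.2
LOWER_THRESHOLD = 0.023

NOT_APPLICABLE = None


class Tier(str, Enum):
    ABOVE = "above_0.2"
    BETWEEN = "between_0.023_and_0.2"
    BELOW = "below_0.023"

    @property
    def marker(self) -> str:
        return {"above_0.2": "**", "between_0.023_and_0.2": "*", "below_0.023": ""}[
            self.value
        ]


@dataclass(frozen=True)
class PenaltyTables:
    """Position- and identity-indexed activity fractions."""

    mismatch: dict   # (pos 1..20, guide_base, target_base) -> activity
    pam: dict        # trinucleotide pattern e.g. "NGG" suffix keyed -> activity
    insertion: dict  # (pos, inserted_base) -> activity
    deletion: dict   # (pos, guide_base) -> activity
    checksum: str = ""

    def pam_activity(self, trinucleotide: str) -> float:
        key = "N" + trinucleotide[1:].upper()
        try:
            return self.pam[key]
        except KeyError:
            raise PenaltyLookupError(f"pam:{trinucleotide}")

    def mismatch_activity(self, pos: int, guide_base: str, target_base: str) -> float:
        try:
            return self.mismatch[(pos, guide_base, target_base)]
        except KeyError:
            raise PenaltyLookupError(f"mismatch:{pos}:{guide_base}>{target_base}")

    def insertion_activity(self, pos: int, inserted_base: str) -> float:
        try:
            return self.insertion[(pos, inserted_base)]
        except KeyError:
            raise PenaltyLookupError(f"insertion:{pos}:{inserted_base}")

    def deletion_activity(self, pos: int, guide_base: str) -> float:
        try:
            return self.deletion[(pos, guide_base)]
        except KeyError:
            raise PenaltyLookupError(f"deletion:{pos}:{guide_base}")


@dataclass(frozen=True)
class ScoreResult:
    cfd_mm: float
    cfd_indel: Optional[float]  # None when the alignment has no indels
    cfd_final: float
    tier: Tier

    def render(self, ndigits: int = 3) -> dict:
        """Display form: 3-dp rounding, '-' for an absent indel score."""
        return {
            "cfd_mm": round(self.cfd_mm, ndigits),
            "cfd_indel": "-" if self.cfd_indel is None else round(self.cfd_indel, ndigits),
            "cfd_final": round(self.cfd_final, ndigits),
            "tier": self.tier.marker,
        }


def load_penalties(resource: Union[str, Path, None] = None) -> PenaltyTables:
    """Load penalty tables from a TSV resource.

    Columns: kind, position, guide_base, target_base, activity.  The
    default resource ships with the package; its SHA-256 is logged so a
    run can be tied to the exact table version.
    """
    if resource is None:
        ref = importlib_resources.files("offpop.resources") / DEFAULT_RESOURCE
        text = ref.read_text()
        name = DEFAULT_RESOURCE
    else:
        text = Path(resource).read_text()
        name = str(resource)
    checksum = hashlib.sha256(text.encode()).hexdigest()
    log.info("penalty resource %s sha256=%s", name, checksum)

    mismatch, pam, insertion, deletion = {}, {}, {}, {}
    reader = csv.DictReader(text.splitlines(), delimiter="\t")
    required = {"kind", "position", "guide_base", "target_base", "activity"}
    if reader.fieldnames is None or not required.issubset(reader.fieldnames):
        raise ValidationError(
            f"penalty resource must have columns {sorted(required)}"
        )
    for lineno, row in enumerate(reader, start=2):
        try:
            activity = float(row["activity"])
        except (TypeError, ValueError):
            raise ValidationError(f"{name}:{lineno}: malformed activity")
        if not 0.0 <= activity <= 1.0:
            raise ValidationError(f"{name}:{lineno}: activity outside [0,1]")
        kind = row["kind"]
        if kind == "mismatch":
            key = (int(row["position"]), row["guide_base"], row["target_base"])
            mismatch[key] = activity
        elif kind == "pam":
            pam[row["target_base"]] = activity
        elif kind == "insertion":
            insertion[(int(row["position"]), row["target_base"])] = activity
        elif kind == "deletion":
            deletion[(int(row["position"]), row["guide_base"])] = activity
        else:
            raise ValidationError(f"{name}:{lineno}: unknown kind {kind!r}")

    for pos in range(1, 21):
        for g in "ACGT":
            for t in "ACGT":
                if g != t and (pos, g, t) not in mismatch:
                    raise ValidationError(
                        f"penalty resource incomplete: missing mismatch "
                        f"entry ({pos},{g},{t})"
                    )
    return PenaltyTables(
        mismatch=mismatch, pam=pam, insertion=insertion, deletion=deletion,
        checksum=checksum,
    )


def uniform_tables(value: float = 0.5, pam_value: float = 1.0) -> PenaltyTables:
    """Synthetic tables with every penalty equal; for property tests."""
    mismatch = {
        (p, g, t): value
        for p in range(1, 21) for g in "ACGT" for t in "ACGT" if g != t
    }
    pam = {("N" + a + b): (1.0 if (a, b) == ("G", "G") else pam_value)
           for a in "ACGT" for b in "ACGT"}
    insertion = {(p, b): value for p in range(1, 22) for b in "ACGT"}
    deletion = {(p, g): value for p in range(1, 21) for g in "ACGT"}
    return PenaltyTables(mismatch, pam, insertion, deletion, checksum="uniform")


def cfd_mismatch(a: GuideAlignment, t: PenaltyTables) -> float:
    """Product of mismatch penalties times the PAM penalty."""
    score = t.pam_activity(a.pam_observed)
    for c in a.columns:
        if c.op == MISMATCH:
            score *= t.mismatch_activity(c.guide_pos, c.guide_base, c.target_base)
    return score


def cfd_indel(a: GuideAlignment, t: PenaltyTables) -> Optional[float]:
    """Product of indel penalties; ``None`` when the alignment has none."""
    if a.indels == 0:
        return NOT_APPLICABLE
    score = 1.0
    for c in a.columns:
        if c.op == INSERTION:
            score *= t.insertion_activity(c.target_pos, c.target_base)
        elif c.op == DELETION:
            score *= t.deletion_activity(c.guide_pos, c.guide_base)
    return score


def cfd_final(mm: float, indel: Optional[float]) -> ScoreResult:
    """Combine the two event probabilities and classify the tier."""
    if not 0.0 <= mm <= 1.0 or (indel is not None and not 0.0 <= indel <= 1.0):
        raise ValidationError("score components must lie in [0,1]")
    final = mm if indel is None else mm * indel
    if final >= UPPER_THRESHOLD:
        tier = Tier.ABOVE
    elif final >= LOWER_THRESHOLD:
        tier = Tier.BETWEEN
    else:
        tier = Tier.BELOW
    return ScoreResult(cfd_mm=mm, cfd_indel=indel, cfd_final=final, tier=tier)


def score_alignment(
    a: GuideAlignment,
    t: PenaltyTables,
    *,
    allow_noncanonical_pam: bool = False,
    pam_pattern: str = "NGG",
) -> ScoreResult:
    """Full scoring of one alignment.

    Sites whose PAM fails the canonical pattern are only scored when
    explicitly requested; the published analysis scores canonical-PAM
    sites.
    """
    if not allow_noncanonical_pam and not matches_iupac(a.pam_observed, pam_pattern):
        raise ValidationError(
            f"PAM {a.pam_observed} does not match {pam_pattern}; "
            "pass allow_noncanonical_pam=True to score anyway"
        )
    return cfd_final(cfd_mismatch(a, t), cfd_indel(a, t))
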
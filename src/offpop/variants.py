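"""Population-variant overlay on candidate sites.

Variants are genomic plus-strand records with per-population allele
fractions.  Applying a variant substitutes ALT for REF on the genomic
strand, re-orients the window to guide orientation, re-aligns, and
re-scores; the effect classes compare the before/after alignments and
PAM states.  Each variant is evaluated independently (no haplotypes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd
from Bio.Seq import reverse_complement
from cyvcf2 import VCF

from .cfd import PenaltyTables, ScoreResult, cfd_final, cfd_indel, cfd_mismatch
from .errors import PenaltyLookupError
from .candidates import FilterPolicy, align_site
from .errors import DataIntegrityError, ParameterError, ValidationError
from .guide import (
    MAX_CANDIDATE_LEN,
    MIN_CANDIDATE_LEN,
    PAM_LEN,
    CandidateSite,
    GuideRNA,
    align,
    pam_check,
    seed_conserved,
)

log = logging.getLogger(__name__)

POLYMORPHIC_THRESHOLD = 0.01

EFFECT_INCREASE_MM = "increase_mismatches"
EFFECT_DECREASE_MM = "decrease_mismatches"
EFFECT_INCREASE_INDELS = "increase_indels"
EFFECT_SEED_DISRUPTED = "seed_disrupted"
EFFECT_PAM_DISRUPTED = "pam_disrupted"
EFFECT_PAM_CREATED = "pam_created"
EFFECT_NO_CHANGE = "no_change"


@dataclass
class VariantRecord:
    """One biallelic population variant with per-population frequencies."""

    chrom: str
    pos: int  # 1-based, as in VCF
    ref: str
    alt: str
    af: Dict[str, float] = field(default_factory=dict)
    source: str = ""
    polymorphic: bool = False
    populations_over_threshold: Set[str] = field(default_factory=set)

    def __post_init__(self):
        if not self.ref:
            raise ValidationError("REF must be nonempty")
        for pop, f in self.af.items():
            if not 0.0 <= f <= 1.0:
                raise ValidationError(f"AF for {pop} outside [0,1]: {f}")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)

    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    def length_change(self) -> int:
        return len(self.alt) - len(self.ref)


@dataclass
class OverlayResult:
    site_id: str
    variant: VariantRecord
    new_seq: str
    m_i_before: Tuple[int, int]
    m_i_after: Tuple[int, int]
    score_before: Optional[ScoreResult]
    score_after: Optional[ScoreResult]
    effects: Set[str]
    pam_before: str = ""
    pam_after: str = ""


def read_frequencies(path, population_map: Dict[str, str]) -> List[VariantRecord]:
    """Read population variants from a VCF or a long-format TSV.

    ``population_map`` maps population labels to VCF INFO keys (e.g.
    ``{"A": "AFR_AF"}``).  For TSV input (columns chrom, pos, ref, alt,
    population, af) the map's keys select which population labels are
    kept.  Populations absent from a record are absent from its ``af``,
    not zero.
    """
    if not population_map:
        raise ValidationError("population_map must not be empty")
    path = Path(path)
    if path.suffix in {".tsv", ".txt", ".csv"}:
        return _read_frequencies_tsv(path, population_map)
    return _read_frequencies_vcf(path, population_map)


def _read_frequencies_vcf(path, population_map) -> List[VariantRecord]:
    records = []
    vcf = VCF(str(path))
    info_keys = {hdr["ID"] for hdr in vcf.header_iter() if hdr["HeaderType"] == "INFO"}
    for pop, key in population_map.items():
        if key not in info_keys:
            raise ValidationError(f"INFO key {key!r} for population {pop!r} "
                                  f"not declared in {path}")
    for v in vcf:
        for alt_idx, alt in enumerate(v.ALT):
            af = {}
            bad = False
            for pop, key in population_map.items():
                raw = v.INFO.get(key)
                if raw is None:
                    continue
                if isinstance(raw, tuple):
                    raw = raw[alt_idx]
                try:
                    value = float(raw)
                except (TypeError, ValueError):
                    log.warning("skipping %s:%s malformed %s", v.CHROM, v.POS, key)
                    bad = True
                    break
                af[pop] = value
            if bad:
                continue
            records.append(
                VariantRecord(
                    chrom=v.CHROM, pos=v.POS, ref=v.REF, alt=alt,
                    af=af, source=str(path.name),
                )
            )
    return records


def _read_frequencies_tsv(path, population_map) -> List[VariantRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    needed = {"chrom", "pos", "ref", "alt", "population", "af"}
    if not needed.issubset(df.columns):
        raise ValidationError(f"{path}: TSV needs columns {sorted(needed)}")
    unknown = set(df["population"]) - set(population_map)
    if unknown:
        raise ValidationError(f"{path}: unmapped population labels {sorted(unknown)}")
    records: Dict[tuple, VariantRecord] = {}
    for row in df.itertuples(index=False):
        key = (row.chrom, int(row.pos), row.ref, row.alt)
        rec = records.get(key)
        if rec is None:
            rec = records[key] = VariantRecord(
                chrom=row.chrom, pos=int(row.pos), ref=row.ref, alt=row.alt,
                source=str(Path(path).name),
            )
        try:
            rec.af[row.population] = float(row.af)
        except (TypeError, ValueError):
            log.warning("skipping malformed AF at %s:%s", row.chrom, row.pos)
    return list(records.values())


def polymorphic_filter(
    records: Iterable[VariantRecord],
    threshold: float = POLYMORPHIC_THRESHOLD,
    populations: Set[str] = frozenset({"E", "LA", "A"}),
) -> List[VariantRecord]:
    """Flag records reaching ``threshold`` in at least one population.

    The worldwide frequency never triggers the rule unless explicitly
    listed in ``populations``.
    """
    if not 0.0 < threshold < 1.0:
        raise ParameterError("threshold must lie in (0,1)")
    if not populations:
        raise ValidationError("populations must not be empty")
    out = []
    for rec in records:
        over = {p for p in populations if rec.af.get(p, 0.0) >= threshold}
        rec.populations_over_threshold = over
        rec.polymorphic = bool(over)
        out.append(rec)
    return out


def _window_with_flanks(site: CandidateSite) -> Tuple[str, int]:
    """Genomic plus-strand sequence of site plus flanks, and window offset."""
    return site.flank5 + site.genomic_seq + site.flank3, len(site.flank5)


def apply_variant(site: CandidateSite, v: VariantRecord) -> str:
    """Apply ALT on the genomic strand and return the new guide-oriented seq.

    The REF allele must lie inside the site window (extended by any
    stored flanks) and match the stored sequence.  Length-changing
    variants shrink or grow the window; if the result leaves the
    supported 21-25 nt range the window is re-derived from the flanks,
    and the variant is rejected when the flanks cannot cover it.
    """
    if v.chrom != site.chrom:
        raise ValidationError(f"{site.id}: variant on {v.chrom}, site on {site.chrom}")
    window, w_off = _window_with_flanks(site)
    # offset of REF within the extended window
    off = (v.pos - 1) - (site.start - len(site.flank5))
    if off < 0 or off + len(v.ref) > len(window):
        raise ValidationError(
            f"{site.id}: variant {v.chrom}:{v.pos} REF extends outside the "
            "site window and available flanks"
        )
    if window[off : off + len(v.ref)] != v.ref:
        raise DataIntegrityError(
            f"{site.id}: REF {v.ref} does not match stored sequence "
            f"{window[off:off + len(v.ref)]} at {v.chrom}:{v.pos}"
        )
    mutated = window[:off] + v.alt + window[off + len(v.ref):]
    # re-derive the candidate window around the variant's length change
    delta = len(v.alt) - len(v.ref)
    win_lo, win_hi = w_off, w_off + (site.end - site.start)
    if off + len(v.ref) <= win_lo:  # entirely in the 5' flank
        lo, hi = win_lo + delta, win_hi + delta
    elif off >= win_hi:  # entirely in the 3' flank
        lo, hi = win_lo, win_hi
    else:
        lo, hi = win_lo, win_hi + delta
    new_genomic = mutated[lo:hi]
    if len(new_genomic) < MIN_CANDIDATE_LEN:
        need = MIN_CANDIDATE_LEN - len(new_genomic)
        # extend away from the PAM: genomic 5' for plus sites, 3' for minus
        if site.strand == "+":
            if lo < need:
                raise ValidationError(
                    f"{site.id}: insufficient 5' flank to restore window"
                )
            new_genomic = mutated[lo - need:hi]
        else:
            if hi + need > len(mutated):
                raise ValidationError(
                    f"{site.id}: insufficient 3' flank to restore window"
                )
            new_genomic = mutated[lo:hi + need]
    if len(new_genomic) > MAX_CANDIDATE_LEN:
        # trim PAM-distal excess introduced by an insertion variant
        excess = len(new_genomic) - MAX_CANDIDATE_LEN
        new_genomic = (
            new_genomic[excess:] if site.strand == "+" else new_genomic[:-excess]
        )
    return new_genomic if site.strand == "+" else reverse_complement(new_genomic)


def reevaluate(
    site: CandidateSite,
    v: VariantRecord,
    guide: GuideRNA,
    tables: PenaltyTables,
    policy: FilterPolicy = FilterPolicy(),
) -> OverlayResult:
    """Re-align and re-score a site with one variant applied."""
    before = align_site(guide, site)
    new_seq = apply_variant(site, v)
    after = align(guide, new_seq)

    effects: Set[str] = set()
    if after.mismatches > before.mismatches:
        effects.add(EFFECT_INCREASE_MM)
    elif after.mismatches < before.mismatches:
        effects.add(EFFECT_DECREASE_MM)
    if after.indels > before.indels:
        effects.add(EFFECT_INCREASE_INDELS)
    if seed_conserved(before, policy.seed_len) and not seed_conserved(after, policy.seed_len):
        effects.add(EFFECT_SEED_DISRUPTED)
    pam_ok_before = pam_check(before, policy.pam_pattern)
    pam_ok_after = pam_check(after, policy.pam_pattern)
    if pam_ok_before and not pam_ok_after:
        effects.add(EFFECT_PAM_DISRUPTED)
    elif not pam_ok_before and pam_ok_after:
        effects.add(EFFECT_PAM_CREATED)
    if not effects and before.columns == after.columns \
            and before.pam_observed == after.pam_observed:
        effects.add(EFFECT_NO_CHANGE)

    def _score(a, label):
        # indels outside the tabulated positions (e.g. guide position 1)
        # leave the score undefined without invalidating the overlay
        try:
            return cfd_final(cfd_mismatch(a, tables), cfd_indel(a, tables))
        except PenaltyLookupError as exc:
            log.warning("%s: %s score unavailable: %s", site.id, label, exc)
            return None

    score_before = _score(before, "pre-variant")
    score_after = _score(after, "post-variant")
    return OverlayResult(
        site_id=site.id,
        variant=v,
        new_seq=new_seq,
        m_i_before=before.m_i,
        m_i_after=after.m_i,
        score_before=score_before,
        score_after=score_after,
        effects=effects,
        pam_before=before.pam_observed,
        pam_after=after.pam_observed,
    )


def population_privacy(
    records: Iterable[VariantRecord],
    populations: Set[str] = frozenset({"E", "LA", "A"}),
    threshold: float = POLYMORPHIC_THRESHOLD,
) -> dict:
    """Venn-style private/shared counts over polymorphic sites.

    A site is private to population p iff its frequency reaches the
    threshold in p and in no other configured population.
    """
    populations = set(populations)
    private = {p: 0 for p in sorted(populations)}
    shared = 0
    total = 0
    for rec in records:
        if not rec.polymorphic:
            continue
        over = {p for p in populations if rec.af.get(p, 0.0) >= threshold}
        if not over:
            continue
        total += 1
        if len(over) == 1:
            private[next(iter(over))] += 1
        else:
            shared += 1
    return {"private": private, "shared": shared, "total": total}
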
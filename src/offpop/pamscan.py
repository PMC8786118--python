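"""Desk-scale genome scan for near-match sites with NNG/NGN pre-PAMs,
and detection of variants that convert them into canonical NGG sites.

The scan is exhaustive over both strands and intended for synthetic or
mini genomes; for full-size genomes, ingest precomputed spacer
alignments (SAM) instead and feed the resulting sites to
:func:`pam_creation_check`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Tuple, Union

from Bio.Seq import reverse_complement
from pyfaidx import Fasta

from .guide import GuideRNA, PAM_LEN, SPACER_LEN, align
from .variants import VariantRecord


@dataclass(frozen=True)
class ProtoPamSite:
    """A gapless near-match whose trinucleotide is one base away from NGG."""

    chrom: str
    start: int  # 0-based half-open, spacer+PAM window on the plus strand
    end: int
    strand: str
    mismatches: int
    pam_observed: str  # guide orientation
    pam_class: str     # NNG | NGN
    spacer_seq: str    # guide orientation

    @property
    def candidate_seq(self) -> str:
        return self.spacer_seq + self.pam_observed

    def pam_genomic_interval(self) -> Tuple[int, int]:
        """Plus-strand interval of the PAM trinucleotide."""
        if self.strand == "+":
            return (self.end - PAM_LEN, self.end)
        return (self.start, self.start + PAM_LEN)


def classify_prepam(pam: str) -> str:
    """NNG/NGN classification for a non-NGG trinucleotide; else 'other'."""
    g2, g3 = pam[1] == "G", pam[2] == "G"
    if g2 and g3:
        return "other"  # already canonical
    if g3:
        return "NNG"
    if g2:
        return "NGN"
    return "other"


def _count_mismatches(spacer: str, window: str) -> int:
    return sum(1 for g, t in zip(spacer, window) if g != t)


def scan_near_pam(
    genome: Union[str, Fasta, Dict[str, str]],
    guide: GuideRNA,
    max_mm: int = 6,
    seed_len: int = 5,
) -> List[ProtoPamSite]:
    """Find every gapless near-match followed by an NNG or NGN trinucleotide.

    Criteria: at most ``max_mm`` mismatches, no indels, the ``seed_len``
    PAM-proximal spacer positions exactly conserved, and a PAM that is
    one G short of canonical (so NGG sites are excluded here — they
    belong to the standard pipeline).
    """
    if isinstance(genome, str):
        genome = Fasta(genome)
    spacer = guide.spacer
    seed = spacer[-seed_len:]
    hits: List[ProtoPamSite] = []
    for chrom in (genome.keys() if hasattr(genome, "keys") else genome):
        seq = str(genome[chrom][:]).upper() if isinstance(genome, Fasta) \
            else genome[chrom].upper()
        n = len(seq)
        span = SPACER_LEN + PAM_LEN
        for i in range(0, n - span + 1):
            window = seq[i : i + span]
            # plus strand
            if window[SPACER_LEN - seed_len : SPACER_LEN] == seed:
                pam = window[SPACER_LEN:]
                klass = classify_prepam(pam)
                if klass != "other":
                    mm = _count_mismatches(spacer, window[:SPACER_LEN])
                    if mm <= max_mm:
                        hits.append(ProtoPamSite(
                            chrom, i, i + span, "+", mm, pam, klass,
                            window[:SPACER_LEN],
                        ))
            # minus strand: guide-orientation sequence is the revcomp
            rc = reverse_complement(window)
            if rc[SPACER_LEN - seed_len : SPACER_LEN] == seed:
                pam = rc[SPACER_LEN:]
                klass = classify_prepam(pam)
                if klass != "other":
                    mm = _count_mismatches(spacer, rc[:SPACER_LEN])
                    if mm <= max_mm:
                        hits.append(ProtoPamSite(
                            chrom, i, i + span, "-", mm, pam, klass,
                            rc[:SPACER_LEN],
                        ))
    return hits


def pam_creation_check(
    sites: Iterable[ProtoPamSite],
    variants: Iterable[VariantRecord],
) -> List[Tuple[ProtoPamSite, VariantRecord, str]]:
    """Pairs (site, variant, created_pam) where ALT makes the PAM NGG.

    Only length-preserving substitutions inside the PAM trinucleotide
    are considered.  The check is positional: the variant base is placed
    at its offset in the guide-oriented PAM and the result must match
    NGG.
    """
    variants = list(variants)
    out = []
    for site in sites:
        plo, phi = site.pam_genomic_interval()
        for v in variants:
            if v.chrom != site.chrom or len(v.ref) != len(v.alt):
                continue
            lo, hi = v.pos - 1, v.pos - 1 + len(v.ref)
            if lo < plo or hi > phi:
                continue
            pam_genomic = site.pam_observed if site.strand == "+" \
                else reverse_complement(site.pam_observed)
            if pam_genomic[lo - plo : hi - plo] != v.ref:
                continue  # REF disagrees with the stored PAM bases
            new = pam_genomic[: lo - plo] + v.alt + pam_genomic[hi - plo:]
            new_pam = new if site.strand == "+" else reverse_complement(new)
            if new_pam[1] == "G" and new_pam[2] == "G" and new_pam != site.pam_observed:
                out.append((site, v, new_pam))
    return out
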
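"""Ingest, merge, filter, and annotate candidate off-target tables.

The unified candidate TSV schema has columns
``id, chrom, start, end, strand, sequence, source, annotation``
with 0-based half-open coordinates; the ``sequence`` column is in guide
orientation and may contain ``-`` gap characters.  Per-predictor
converters are out of scope: whatever produced the table is named in
``source``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .errors import DataIntegrityError, ValidationError
from .guide import (
    CandidateSite,
    GuideAlignment,
    GuideRNA,
    align,
    parse_gapped,
    pam_check,
    seed_conserved,
)

log = logging.getLogger(__name__)

CANDIDATE_COLUMNS = [
    "id", "chrom", "start", "end", "strand", "sequence", "source", "annotation",
]


@dataclass(frozen=True)
class FilterPolicy:
    """Inclusion criteria; the defaults reproduce the published audit."""

    max_mismatches: int = 6
    max_indels: int = 2
    require_seed: bool = True
    seed_len: int = 5
    pam_pattern: str = "NGG"


@dataclass(frozen=True)
class RepeatFlag:
    status: str  # inside | near | none
    element: str = ""


@dataclass
class AlignedSite:
    """A candidate together with its guide alignment."""

    site: CandidateSite
    alignment: GuideAlignment


@dataclass
class FilterOutcome:
    retained: List[AlignedSite]
    rejected: List[Tuple[CandidateSite, str]]  # (site, reason)


def read_candidates(path) -> List[CandidateSite]:
    """Read one unified candidate TSV into :class:`CandidateSite` records."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "chrom": str})
    missing = set(CANDIDATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    sites = []
    for row in df.itertuples(index=False):
        annotation = row.annotation
        gene = None
        if isinstance(annotation, str) and annotation.startswith("genic:"):
            gene = annotation.split(":", 1)[1]
            annotation = "genic"
        sites.append(
            CandidateSite(
                id=str(row.id),
                chrom=row.chrom,
                start=int(row.start),
                end=int(row.end),
                strand=row.strand,
                observed_seq=row.sequence,
                sources={row.source} if isinstance(row.source, str) else set(),
                annotation=annotation if isinstance(annotation, str) else "unknown",
                gene=gene,
            )
        )
    return sites


def merge_predictions(tables: Sequence) -> List[CandidateSite]:
    """Merge candidate lists/TSVs into one record per locus.

    Records agreeing on (chrom, start, end, strand) are collapsed with
    their sources unioned; conflicting sequences at one locus are a data
    integrity error.
    """
    merged: Dict[tuple, CandidateSite] = {}
    for table in tables:
        sites = table if isinstance(table, list) else read_candidates(table)
        for s in sites:
            key = (s.chrom, s.start, s.end, s.strand)
            if key in merged:
                kept = merged[key]
                if kept.ungapped != s.ungapped:
                    raise DataIntegrityError(
                        f"conflicting sequences at {s.chrom}:{s.start}-{s.end}"
                        f"({s.strand}): {kept.ungapped} vs {s.ungapped}"
                    )
                kept.sources |= s.sources
                if kept.annotation == "unknown":
                    kept.annotation, kept.gene = s.annotation, s.gene
            else:
                merged[key] = s
    return sorted(merged.values(), key=lambda s: (s.chrom, s.start, s.end, s.strand))


def align_site(guide: GuideRNA, site: CandidateSite) -> GuideAlignment:
    """Alignment entry point: gapped/markup notation if present, else the DP."""
    seq = site.observed_seq
    if "-" in seq or any(c.islower() for c in seq) or len(seq) == 23:
        return parse_gapped(guide, seq)
    return align(guide, seq)


def apply_filters(
    sites: Iterable[CandidateSite],
    guide: GuideRNA,
    policy: FilterPolicy = FilterPolicy(),
) -> FilterOutcome:
    """Apply the mismatch/indel/SEED/PAM inclusion criteria.

    Unalignable sequences are recorded as rejected-with-reason rather
    than raised.
    """
    retained, rejected = [], []
    for site in sites:
        try:
            a = align_site(guide, site)
        except ValidationError as exc:
            rejected.append((site, f"unalignable: {exc}"))
            continue
        m, i = a.mismatches, a.indels
        if m > policy.max_mismatches:
            rejected.append((site, f"mismatches {m} > {policy.max_mismatches}"))
        elif i > policy.max_indels:
            rejected.append((site, f"indels {i} > {policy.max_indels}"))
        elif policy.require_seed and not seed_conserved(a, policy.seed_len):
            rejected.append((site, "seed not conserved"))
        elif not pam_check(a, policy.pam_pattern):
            rejected.append((site, f"PAM {a.pam_observed} fails {policy.pam_pattern}"))
        else:
            retained.append(AlignedSite(site=site, alignment=a))
    return FilterOutcome(retained=retained, rejected=rejected)


def _read_intervals(path) -> pd.DataFrame:
    """Read gene/repeat intervals from BED or GFF3 into a 0-based table."""
    path = Path(path)
    if path.suffix.lower() in {".gff", ".gff3", ".gtf"}:
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["chrom", "source", "type", "start", "end", "score",
                   "strand", "frame", "attributes"],
            dtype={"chrom": str},
        )
        keep = df["type"].isin(["gene", "pseudogene"])
        df = df[keep].copy()
        name = df["attributes"].str.extract(r"Name=([^;]+)")[0]
        name = name.fillna(df["attributes"].str.extract(r"gene_name=([^;]+)")[0])
        df["name"] = name.fillna(df["attributes"].str.extract(r"ID=([^;]+)")[0])
        df["is_pseudo"] = df["type"].eq("pseudogene")
        df["start"] = df["start"].astype(int) - 1  # GFF3 is 1-based inclusive
        df["end"] = df["end"].astype(int)
    elif path.suffix.lower() == ".out":
        df = _read_repeatmasker_out(path)
    else:  # BED: 0-based half-open
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None, dtype={0: str},
        ).iloc[:, :4]
        df.columns = ["chrom", "start", "end", "name"][: df.shape[1]]
        if "name" not in df.columns:
            df["name"] = ""
        df["is_pseudo"] = df["name"].astype(str).str.contains(
            "pseudogene", case=False, na=False
        )
    return df.sort_values(["chrom", "start", "end"]).reset_index(drop=True)


def _read_repeatmasker_out(path) -> pd.DataFrame:
    """Convert a RepeatMasker ``.out`` whitespace table to intervals."""
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts or not parts[0].isdigit():
                continue  # header / blank lines
            chrom, start, end = parts[4], int(parts[5]), int(parts[6])
            name = parts[9] if len(parts) > 9 else ""
            rows.append((chrom, start - 1, end, name, False))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "is_pseudo"])


def _overlapping(df: pd.DataFrame, chrom: str, start: int, end: int) -> pd.DataFrame:
    sub = df[df["chrom"] == chrom]
    return sub[(sub["start"] < end) & (sub["end"] > start)]


def annotate_genic(
    sites: Iterable[CandidateSite], gene_intervals
) -> List[CandidateSite]:
    """Label each site genic(gene), pseudogene, or intergenic (any overlap)."""
    df = gene_intervals if isinstance(gene_intervals, pd.DataFrame) \
        else _read_intervals(gene_intervals)
    known_chroms = set(df["chrom"])
    out = []
    for site in sites:
        if site.chrom not in known_chroms:
            log.warning("chromosome %s absent from annotation", site.chrom)
            site.annotation, site.gene = "unknown", None
        else:
            hits = _overlapping(df, site.chrom, site.start, site.end)
            if len(hits):
                first = hits.iloc[0]
                if bool(first.get("is_pseudo", False)):
                    site.annotation = "pseudogene"
                else:
                    site.annotation = "genic"
                site.gene = str(first["name"]) if pd.notna(first["name"]) else None
            else:
                site.annotation, site.gene = "intergenic", None
        out.append(site)
    return out


def find_duplicate_sequences(
    sites: Iterable[AlignedSite],
) -> Dict[str, List[AlignedSite]]:
    """Group retained sites sharing an identical ungapped sequence.

    Keys are the ungapped guide-orientation sequences; only groups with
    at least two distinct loci are returned.
    """
    groups: Dict[str, List[AlignedSite]] = {}
    for a in sites:
        groups.setdefault(a.site.ungapped, []).append(a)
    return {
        seq: members
        for seq, members in groups.items()
        if len({(m.site.chrom, m.site.start, m.site.end) for m in members}) >= 2
    }


def flag_repeats(
    sites: Iterable[CandidateSite], repeat_intervals, flank: int = 200
) -> Dict[str, RepeatFlag]:
    """Classify repeat overlap: inside the site, near (within +/-flank), none."""
    df = repeat_intervals if isinstance(repeat_intervals, pd.DataFrame) \
        else _read_intervals(repeat_intervals)
    flags = {}
    for site in sites:
        inside = _overlapping(df, site.chrom, site.start, site.end)
        if len(inside):
            flags[site.id] = RepeatFlag("inside", str(inside.iloc[0]["name"]))
            continue
        around = _overlapping(
            df, site.chrom, max(0, site.start - flank), site.end + flank
        )
        if len(around):
            flags[site.id] = RepeatFlag("near", str(around.iloc[0]["name"]))
        else:
            flags[site.id] = RepeatFlag("none")
    return flags
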
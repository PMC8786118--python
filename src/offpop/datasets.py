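"""Bundled demonstration dataset: the IDUA W402X guide and its published
candidate off-target sites and site variants.

The candidate table carries the sequences exactly as reported (gapped
deletions, lowercase insertion markup).  Genomic coordinates are real
hg19 loci where the source tables print them; rows whose loci were not
printed use placeholder coordinates on ``chrU`` and support
sequence-level analyses only.  Variant rows are keyed by their 1-based
offset in the displayed (gapped) sequence; :func:`variant_for_row`
converts that to a genomic plus-strand :class:`VariantRecord`.
"""

from __future__ import annotations

from importlib import resources as importlib_resources
from typing import Dict, List, Optional, Tuple

import pandas as pd
import yaml

from .candidates import read_candidates
from .errors import ValidationError
from .guide import GAP, CandidateSite, GuideRNA
from .variants import VariantRecord

_PKG = "offpop.data.idua_demo"
POPULATIONS = ("E", "LA", "A")


def _path(name: str):
    return importlib_resources.files(_PKG) / name


def load_demo_guide() -> GuideRNA:
    raw = yaml.safe_load(_path("guide.yaml").read_text())
    return GuideRNA(raw["name"], raw["spacer"], raw.get("pam_pattern", "NGG"))


def load_demo_candidates() -> Tuple[List[CandidateSite], Dict[str, str]]:
    """Candidate sites plus the reported M/I string per id ('.' = unreported)."""
    with importlib_resources.as_file(_path("candidates.tsv")) as p:
        df = pd.read_csv(p, sep="\t", dtype={"id": str})
        expected = dict(zip(df["id"], df["m_i"]))
        sites = read_candidates(p)
    return sites, expected


def load_demo_site_variants() -> pd.DataFrame:
    with importlib_resources.as_file(_path("site_variants.tsv")) as p:
        return pd.read_csv(p, sep="\t", dtype={"site_id": str}, na_values=["."])


def display_offset_to_genomic_pos(
    site: CandidateSite, display_offset: int, ref_len: int = 1
) -> int:
    """1-based VCF POS of a variant given its offset in the displayed seq.

    ``display_offset`` points at the first affected base in the gapped,
    guide-oriented rendering; for minus-strand sites the REF allele spans
    the reverse-complemented window, hence the ``ref_len`` dependence.
    """
    gaps_before = site.observed_seq[:display_offset].count(GAP)
    u1 = display_offset - gaps_before  # 1-based ungapped guide-orientation index
    n = len(site.ungapped)
    if not 1 <= u1 <= n:
        raise ValidationError(f"{site.id}: display offset {display_offset} "
                              "outside the sequence")
    if site.strand == "+":
        return site.start + u1
    return site.start + (n - (u1 - 1) - ref_len) + 1


def variant_for_row(site: CandidateSite, row) -> VariantRecord:
    """Build the genomic VariantRecord a site_variants row describes."""
    ref = str(row.ref)
    pos = display_offset_to_genomic_pos(site, int(row.display_offset), len(ref))
    af = {}
    for pop in POPULATIONS + ("W",):
        value = getattr(row, f"af_{pop}")
        if pd.notna(value):
            af[pop] = float(value)
    return VariantRecord(chrom=site.chrom, pos=pos, ref=ref, alt=str(row.alt),
                         af=af, source="demo")
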
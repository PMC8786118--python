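"""End-to-end audit orchestration and table rendering.

``run_audit`` drives the whole pipeline from one :class:`RunConfig` and
returns a deterministic bundle of data frames plus a summary dict;
``render_tables`` writes them as TSV/JSON.  Scores render at three
decimals with ``-`` for absent indel scores; frequencies render as
percentages at one decimal.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd
import yaml

from . import candidates as cand_mod
from . import variants as var_mod
from .cfd import (
    LOWER_THRESHOLD,
    UPPER_THRESHOLD,
    PenaltyTables,
    load_penalties,
    score_alignment,
)
from .candidates import FilterPolicy
from .errors import ValidationError
from .guide import GuideRNA, position_profile
from .pamscan import pam_creation_check, scan_near_pam
from .variants import POLYMORPHIC_THRESHOLD, polymorphic_filter, population_privacy

log = logging.getLogger(__name__)


@dataclass
class VariantSource:
    path: str
    population_map: Dict[str, str]


@dataclass
class RunConfig:
    guide: GuideRNA
    candidate_tables: List[str]
    genome: Optional[str] = None
    genes: Optional[str] = None
    repeats: Optional[str] = None
    variant_sources: List[VariantSource] = field(default_factory=list)
    policy: FilterPolicy = field(default_factory=FilterPolicy)
    upper_threshold: float = UPPER_THRESHOLD
    lower_threshold: float = LOWER_THRESHOLD
    polymorphic_threshold: float = POLYMORPHIC_THRESHOLD
    populations: tuple = ("E", "LA", "A")
    penalty_resource: Optional[str] = None
    output_dir: str = "offpop_out"
    seed: int = 0

    def __post_init__(self):
        for t in (self.upper_threshold, self.lower_threshold,
                  self.polymorphic_threshold):
            if not 0.0 < t < 1.0:
                raise ValidationError(f"threshold {t} outside (0,1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        g = raw["guide"]
        guide = GuideRNA(g.get("name", "guide"), g["spacer"],
                         g.get("pam_pattern", "NGG"))
        pol = raw.get("policy", {})
        policy = FilterPolicy(
            max_mismatches=pol.get("max_mismatches", 6),
            max_indels=pol.get("max_indels", 2),
            require_seed=pol.get("require_seed", True),
            seed_len=pol.get("seed_len", 5),
            pam_pattern=pol.get("pam_pattern", "NGG"),
        )
        thresholds = raw.get("thresholds", {})
        inputs = raw.get("inputs", {})
        sources = [
            VariantSource(v["path"], v["population_map"])
            for v in inputs.get("variants", [])
        ]
        cfg = cls(
            guide=guide,
            candidate_tables=inputs.get("candidates", []),
            genome=inputs.get("genome"),
            genes=inputs.get("genes"),
            repeats=inputs.get("repeats"),
            variant_sources=sources,
            policy=policy,
            upper_threshold=thresholds.get("upper", UPPER_THRESHOLD),
            lower_threshold=thresholds.get("lower", LOWER_THRESHOLD),
            polymorphic_threshold=thresholds.get("polymorphic",
                                                 POLYMORPHIC_THRESHOLD),
            populations=tuple(raw.get("populations", ("E", "LA", "A"))),
            penalty_resource=raw.get("penalty_resource"),
            output_dir=raw.get("output_dir", "offpop_out"),
            seed=raw.get("seed", 0),
        )
        for p in cfg.candidate_tables + [cfg.genome, cfg.genes, cfg.repeats] + [
            s.path for s in cfg.variant_sources
        ]:
            if p is not None and not Path(p).exists():
                raise ValidationError(f"configured path does not exist: {p}")
        return cfg


def _checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _mi(a) -> str:
    return f"{a.mismatches}/{a.indels}"


def run_audit(config: RunConfig) -> dict:
    """Run the full audit; returns the report bundle.

    Any stage failure aborts with the stage name and the offending
    record id in the exception message.
    """
    bundle: dict = {"inputs": {}, "seed": config.seed}
    for p in config.candidate_tables:
        bundle["inputs"][str(p)] = _checksum(p)

    tables = load_penalties(config.penalty_resource)
    bundle["penalty_checksum"] = tables.checksum

    stage = "merge"
    try:
        sites = cand_mod.merge_predictions(list(config.candidate_tables))
        stage = "filter"
        outcome = cand_mod.apply_filters(sites, config.guide, config.policy)
        if config.genes:
            stage = "annotate"
            cand_mod.annotate_genic([a.site for a in outcome.retained],
                                    config.genes)
        stage = "score"
        score_rows = []
        for a in outcome.retained:
            s = score_alignment(a.alignment, tables,
                                pam_pattern=config.policy.pam_pattern)
            rendered = s.render()
            score_rows.append({
                "id": a.site.id,
                "sequence": a.site.observed_seq,
                "m_i": _mi(a.alignment),
                "localization": a.site.locus(),
                "annotation": (
                    f"genic:{a.site.gene}" if a.site.annotation == "genic"
                    and a.site.gene else a.site.annotation
                ),
                "cfd_mm": rendered["cfd_mm"],
                "cfd_indel": rendered["cfd_indel"],
                "cfd_final": rendered["cfd_final"],
                "tier": rendered["tier"],
                "_final_unrounded": s.cfd_final,
                "_indels": a.alignment.indels,
                "_mismatches": a.alignment.mismatches,
            })
        scores = pd.DataFrame(score_rows)
        stage = "duplicates"
        dup_groups = cand_mod.find_duplicate_sequences(outcome.retained)
        stage = "repeats"
        repeat_flags = (
            cand_mod.flag_repeats([a.site for a in outcome.retained],
                                  config.repeats)
            if config.repeats else {}
        )
    except Exception as exc:
        raise type(exc)(f"stage {stage}: {exc}") from exc

    # variant overlay
    overlay_rows, all_records = [], []
    by_key: dict = {}
    for src in config.variant_sources:
        stage = f"variants:{src.path}"
        for rec in var_mod.read_frequencies(src.path, src.population_map):
            if rec.key in by_key:  # same site listed by several sources
                by_key[rec.key].af.update(rec.af)
            else:
                by_key[rec.key] = rec
                all_records.append(rec)
    overlapping = []
    for rec in all_records:
        for a in outcome.retained:
            site = a.site
            if rec.chrom != site.chrom:
                continue
            if site.start - len(site.flank5) <= rec.pos - 1 < site.end + len(site.flank3):
                overlapping.append((a, rec))
    polymorphic_filter(
        [rec for _, rec in overlapping],
        threshold=config.polymorphic_threshold,
        populations=set(config.populations),
    )
    for a, rec in overlapping:
        stage = f"overlay:{a.site.id}"
        try:
            res = var_mod.reevaluate(a.site, rec, config.guide, tables,
                                     config.policy)
        except ValidationError as exc:
            log.warning("overlay skipped for %s: %s", a.site.id, exc)
            continue
        overlay_rows.append({
            "id": a.site.id,
            "sequence": a.site.observed_seq,
            "ref": rec.ref,
            "alt": rec.alt,
            "no_variant": f"{res.m_i_before[0]}/{res.m_i_before[1]}",
            "variant": f"{res.m_i_after[0]}/{res.m_i_after[1]}",
            "pam_after": res.pam_after,
            "effects": ",".join(sorted(res.effects)),
            "polymorphic": rec.polymorphic,
            **{f"af_{p}": rec.af.get(p) for p in config.populations},
        })

    # genome-wide pre-PAM scan + PAM creation
    created_rows = []
    if config.genome:
        stage = "pamscan"
        proto_sites = scan_near_pam(config.genome, config.guide,
                                    max_mm=config.policy.max_mismatches,
                                    seed_len=config.policy.seed_len)
        for site, rec, new_pam in pam_creation_check(proto_sites, all_records):
            created_rows.append({
                "chrom": site.chrom, "start": site.start, "end": site.end,
                "strand": site.strand, "sequence": site.candidate_seq,
                "ref": rec.ref, "alt": rec.alt, "created_pam": new_pam,
                **{f"af_{p}": rec.af.get(p) for p in config.populations},
            })

    stage = "summary"
    distinct_poly = {r.key for _, r in overlapping if r.polymorphic}
    poly_records = [by_key[k] for k in distinct_poly]
    privacy = population_privacy(poly_records, set(config.populations),
                                 config.polymorphic_threshold)
    profile = (
        position_profile([a.alignment for a in outcome.retained])
        if outcome.retained else None
    )
    summary = {
        "candidates_in": len(sites),
        "retained": len(outcome.retained),
        "rejected": len(outcome.rejected),
        "mismatch_only": int(sum(1 for a in outcome.retained
                                 if a.alignment.indels == 0)),
        "with_indels": int(sum(1 for a in outcome.retained
                               if a.alignment.indels > 0)),
        "duplicate_groups": len(dup_groups),
        "above_upper": int((scores["_final_unrounded"] >= config.upper_threshold).sum())
        if len(scores) else 0,
        "above_lower": int((scores["_final_unrounded"] >= config.lower_threshold).sum())
        if len(scores) else 0,
        "polymorphic_sites": len(distinct_poly),
        "privacy": privacy,
        "pam_created": len(created_rows),
    }
    if not outcome.retained:
        log.warning("no candidates retained; emitting an empty bundle")

    bundle.update({
        "scores": scores,
        "rejected": pd.DataFrame(
            [{"id": s.id, "reason": r} for s, r in outcome.rejected]
        ),
        "duplicates": pd.DataFrame(
            [{"sequence": seq, "n_loci": len(members),
              "loci": ";".join(m.site.locus() for m in members)}
             for seq, members in sorted(dup_groups.items())]
        ),
        "repeats": pd.DataFrame(
            [{"id": sid, "status": f.status, "element": f.element}
             for sid, f in sorted(repeat_flags.items())]
        ),
        "overlay": pd.DataFrame(overlay_rows),
        "pam_created": pd.DataFrame(created_rows),
        "profile": profile,
        "summary": summary,
    })
    return bundle


def render_tables(bundle: dict, outdir, fmt: str = "tsv") -> List[Path]:
    """Write the bundle as TSV + JSON files; bit-stable for fixed input."""
    if fmt not in {"tsv", "json"}:
        raise ValidationError(f"unsupported format {fmt!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def _write_df(name: str, df: Optional[pd.DataFrame]):
        if df is None:
            return
        path = outdir / f"{name}.{ 'tsv' if fmt == 'tsv' else 'json' }"
        df = df.loc[:, [c for c in df.columns if not c.startswith("_")]]
        if fmt == "tsv":
            df.to_csv(path, sep="\t", index=isinstance(df.index, pd.RangeIndex)
                      and df.index.name is not None, float_format="%.3f")
        else:
            path.write_text(df.to_json(orient="records", indent=2))
        written.append(path)

    for name in ("scores", "rejected", "duplicates", "repeats", "overlay",
                 "pam_created"):
        _write_df(name, bundle.get(name))
    if bundle.get("profile") is not None:
        prof = bundle["profile"].reset_index()
        _write_df("profile", prof)
    summary_path = outdir / "summary.json"
    summary_path.write_text(json.dumps(bundle["summary"], indent=2, sort_keys=True))
    written.append(summary_path)
    runlog = outdir / "run_log.json"
    runlog.write_text(json.dumps(
        {"inputs": bundle.get("inputs", {}),
         "penalty_checksum": bundle.get("penalty_checksum"),
         "seed": bundle.get("seed")},
        indent=2, sort_keys=True))
    written.append(runlog)
    return written
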
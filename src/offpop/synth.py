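"""Deterministic synthetic fixtures: genomes, planted off-targets,
annotations, and population variants with known truth.

One :class:`numpy.random.Generator` seeded from a single integer drives
all randomness; the seed is recorded in output headers.  Background
sequence is i.i.d. with a requested GC fraction — no repeat structure,
no linkage, no site-frequency realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement
from pyfaidx import Faidx

from .errors import GenerationError, ParameterError
from .guide import GuideRNA, PAM_LEN, SPACER_LEN, align, seed_conserved
from .candidates import CANDIDATE_COLUMNS

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class IndelSpec:
    kind: str      # "insertion" (extra base in target) or "deletion"
    position: int  # deletion: guide pos 1..20; insertion: gap after guide pos 0..20
    base: str = ""  # inserted base; unused for deletions


@dataclass(frozen=True)
class PlantSpec:
    """Recipe for one planted off-target; truth M/I derive from the fields."""

    site_id: str
    chrom: str
    start: int  # 0-based target position of the candidate window
    strand: str
    mismatches: Dict[int, str] = field(default_factory=dict)  # guide pos -> base
    indels: Tuple[IndelSpec, ...] = ()
    pam: str = "AGG"

    def truth_m_i(self) -> Tuple[int, int]:
        return (len(self.mismatches), len(self.indels))


@dataclass(frozen=True)
class VariantSpec:
    """Recipe for one synthetic population variant."""

    chrom: str
    pos: int  # 1-based
    alt: str
    ref_len: int = 1
    af: Dict[str, float] = field(default_factory=dict)
    intended_effect: str = ""
    site_id: str = ""


def build_planted_sequence(guide: GuideRNA, spec: PlantSpec) -> str:
    """Candidate sequence (guide orientation) a PlantSpec describes."""
    bases = list(guide.spacer)
    for pos, b in spec.mismatches.items():
        if not 1 <= pos <= SPACER_LEN:
            raise GenerationError(f"mismatch position {pos} outside spacer")
        if bases[pos - 1] == b:
            raise GenerationError(f"substituted base equals guide base at {pos}")
        bases[pos - 1] = b
    deletions = sorted(
        (s.position for s in spec.indels if s.kind == "deletion"), reverse=True
    )
    for pos in deletions:
        del bases[pos - 1]
    insertions = sorted(
        (s for s in spec.indels if s.kind == "insertion"),
        key=lambda s: s.position, reverse=True,
    )
    for s in insertions:
        bases.insert(s.position, s.base)
    return "".join(bases) + spec.pam


def make_genome(
    seed: int, length: int, gc: float, out_fasta, chrom: str = "chrS"
) -> Path:
    """Write a reproducible random FASTA (plus .fai index) and return its path."""
    if length < 1000:
        raise ParameterError("genome length must be >= 1000")
    if not 0.0 < gc < 1.0:
        raise ParameterError("gc must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = "".join(rng.choice(BASES, size=length, p=p))
    out_fasta = Path(out_fasta)
    with open(out_fasta, "w") as fh:
        fh.write(f">{chrom} synthetic seed={seed} gc={gc}\n")
        for i in range(0, length, 60):
            fh.write(seq[i : i + 60] + "\n")
    Faidx(str(out_fasta))
    return out_fasta


def plant_sites(
    genome_fasta,
    guide: GuideRNA,
    specs: Sequence[PlantSpec],
    out_fasta,
) -> pd.DataFrame:
    """Overwrite genome windows with planted candidates; return the truth table.

    Loci must not overlap.  Each planted sequence is checked against the
    aligner so the recorded truth (M, I) is guaranteed recoverable.
    """
    from pyfaidx import Fasta

    fa = Fasta(str(genome_fasta))
    chroms = {name: list(str(fa[name][:]).upper()) for name in fa.keys()}

    occupied: List[Tuple[str, int, int]] = []
    rows = []
    for spec in specs:
        cand = build_planted_sequence(guide, spec)
        start, end = spec.start, spec.start + len(cand)
        for c, s, e in occupied:
            if c == spec.chrom and s < end and e > start:
                raise GenerationError(f"{spec.site_id}: overlapping loci")
        occupied.append((spec.chrom, start, end))
        if spec.chrom not in chroms or end > len(chroms[spec.chrom]):
            raise GenerationError(f"{spec.site_id}: locus outside genome")
        genomic = cand if spec.strand == "+" else reverse_complement(cand)
        chroms[spec.chrom][start:end] = list(genomic)
        a = align(guide, cand)
        if a.m_i != spec.truth_m_i():
            raise GenerationError(
                f"{spec.site_id}: aligner recovers {a.m_i}, spec says "
                f"{spec.truth_m_i()}; choose a less ambiguous spec"
            )
        rows.append({
            "id": spec.site_id, "chrom": spec.chrom, "start": start, "end": end,
            "strand": spec.strand, "sequence": cand, "mismatches": a.mismatches,
            "indels": a.indels, "pam": spec.pam,
        })

    out_fasta = Path(out_fasta)
    with open(out_fasta, "w") as fh:
        for name, bases in chroms.items():
            fh.write(f">{name}\n")
            seq = "".join(bases)
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    Faidx(str(out_fasta))
    return pd.DataFrame(rows)


def random_plant_specs(
    seed: int,
    n: int,
    guide: GuideRNA,
    genome_length: int,
    chrom: str = "chrS",
    mm_range: Tuple[int, int] = (4, 6),
    indel_range: Tuple[int, int] = (0, 2),
    seed_len: int = 5,
) -> List[PlantSpec]:
    """Non-overlapping random PlantSpecs with conserved seed regions.

    Specs whose planted sequence admits a cheaper alignment than the
    recipe (gap ambiguity) are resampled, so truth always equals the
    aligner's answer.
    """
    rng = np.random.default_rng(seed)
    specs: List[PlantSpec] = []
    slot = 40  # spacing between planted windows
    max_slots = (genome_length - 100) // slot
    if max_slots < n:
        raise GenerationError("genome too short for requested plant count")
    positions = 50 + slot * rng.choice(max_slots, size=n, replace=False)
    for k in range(n):
        for _ in range(100):  # resample until unambiguous
            n_mm = int(rng.integers(mm_range[0], mm_range[1] + 1))
            n_ind = int(rng.integers(indel_range[0], indel_range[1] + 1))
            editable = list(range(1, SPACER_LEN - seed_len + 1))
            mm_pos = rng.choice(editable, size=n_mm, replace=False)
            mismatches = {}
            for pos in sorted(int(p) for p in mm_pos):
                choices = [b for b in "ACGT" if b != guide.spacer[pos - 1]]
                mismatches[pos] = str(rng.choice(choices))
            kind = str(rng.choice(["insertion", "deletion"])) if n_ind else ""
            remaining = [p for p in editable if p not in mismatches]
            ind_pos = sorted(
                int(p) for p in rng.choice(remaining, size=n_ind, replace=False)
            )
            indels = tuple(
                IndelSpec(kind, p, str(rng.choice(list("ACGT"))))
                for p in ind_pos
            )
            pam = str(rng.choice(list("ACGT"))) + "GG"
            spec = PlantSpec(
                site_id=f"plant{k}",
                chrom=chrom,
                start=int(positions[k]),
                strand=str(rng.choice(["+", "-"])),
                mismatches=mismatches,
                indels=indels,
                pam=pam,
            )
            cand = build_planted_sequence(GuideRNA("g", guide.spacer), spec)
            a = align(guide, cand)
            if a.m_i == spec.truth_m_i() and seed_conserved(a, seed_len):
                specs.append(spec)
                break
        else:  # pragma: no cover
            raise GenerationError("could not realize an unambiguous spec")
    return specs


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def variant_specs_for_plants(
    seed: int,
    plant_specs: Sequence[PlantSpec],
    guide: GuideRNA,
    effect_classes: Sequence[str] = (
        "increase_mismatches", "decrease_mismatches", "seed_disrupted",
        "pam_disrupted", "increase_indels",
    ),
) -> List[VariantSpec]:
    """One VariantSpec per (planted site, requested effect class).

    Positions and alleles are derived from the plant recipe so the
    intended effect is guaranteed realizable; allele frequencies straddle
    the 1% threshold.  Deletion variants are only drawn for gapless
    plants (so the indel count verifiably increases from zero).
    """
    rng = np.random.default_rng(seed)
    out: List[VariantSpec] = []

    def snv(spec: PlantSpec, cand: str, u1: int, new_guide_base: str) -> tuple:
        """(pos, ref, alt) for replacing candidate base u1 (1-based)."""
        old = cand[u1 - 1]
        if spec.strand == "+":
            return spec.start + u1, old, new_guide_base
        n = len(cand)
        return spec.start + (n - u1) + 1, _COMP[old], _COMP[new_guide_base]

    for spec in plant_specs:
        cand = build_planted_sequence(guide, spec)
        n = len(cand)
        if spec.indels:
            continue  # keep the u1 <-> guide-position mapping trivial
        af_hi = round(float(rng.uniform(0.011, 0.5)), 3)
        af_lo = round(float(rng.uniform(0.0, 0.009)), 3)
        for effect in effect_classes:
            if effect == "decrease_mismatches":
                if not spec.mismatches:
                    continue
                pos1 = int(rng.choice(sorted(spec.mismatches)))
                pos, ref, alt = snv(spec, cand, pos1, guide.spacer[pos1 - 1])
            elif effect == "increase_mismatches":
                matched = [p for p in range(1, SPACER_LEN - 5 + 1)
                           if p not in spec.mismatches]
                pos1 = int(rng.choice(matched))
                choices = [b for b in "ACGT" if b != guide.spacer[pos1 - 1]]
                pos, ref, alt = snv(spec, cand, pos1, str(rng.choice(choices)))
            elif effect == "seed_disrupted":
                pos1 = int(rng.integers(SPACER_LEN - 4, SPACER_LEN + 1))
                choices = [b for b in "ACGT" if b != guide.spacer[pos1 - 1]]
                pos, ref, alt = snv(spec, cand, pos1, str(rng.choice(choices)))
            elif effect == "pam_disrupted":
                u1 = n - 1 if rng.random() < 0.5 else n  # a G of the NGG
                choices = [b for b in "ACGT" if b != "G"]
                pos, ref, alt = snv(spec, cand, u1, str(rng.choice(choices)))
            elif effect == "increase_indels":
                u1 = int(rng.integers(3, SPACER_LEN - 5))  # keep seed intact
                genomic = cand if spec.strand == "+" else _rc(cand)
                g0 = (u1 - 1) if spec.strand == "+" else (n - u1)
                pos = spec.start + g0  # anchor base precedes the deleted one
                ref = genomic[g0 - 1 : g0 + 1]
                alt = genomic[g0 - 1]
            else:
                raise GenerationError(f"unknown effect class {effect!r}")
            out.append(VariantSpec(
                chrom=spec.chrom, pos=pos, alt=alt, ref_len=len(ref),
                af={"A": af_hi, "E": af_lo, "LA": af_lo, "W": af_hi},
                intended_effect=effect, site_id=spec.site_id,
            ))
    return out


def _rc(seq: str) -> str:
    return reverse_complement(seq)


def make_vcf(
    specs: Sequence[VariantSpec],
    genome_fasta,
    out_vcf,
    population_keys: Optional[Dict[str, str]] = None,
    seed: Optional[int] = None,
) -> Path:
    """Write a VCF with per-population AF INFO keys; REF read from the genome."""
    from pyfaidx import Fasta

    population_keys = population_keys or {
        "E": "EUR_AF", "LA": "AMR_AF", "A": "AFR_AF", "W": "AF",
    }
    fa = Fasta(str(genome_fasta))
    lines = [
        "##fileformat=VCFv4.2",
        f"##source=offpop-synth{'' if seed is None else f' seed={seed}'}",
    ]
    for pop, key in population_keys.items():
        lines.append(
            f'##INFO=<ID={key},Number=A,Type=Float,'
            f'Description="Allele frequency, population {pop}">'
        )
    for name in fa.keys():
        lines.append(f"##contig=<ID={name},length={len(fa[name])}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for i, spec in enumerate(sorted(specs, key=lambda s: (s.chrom, s.pos))):
        ref = str(fa[spec.chrom][spec.pos - 1 : spec.pos - 1 + spec.ref_len]).upper()
        if not ref or len(ref) != spec.ref_len:
            raise GenerationError(f"REF at {spec.chrom}:{spec.pos} outside genome")
        if ref == spec.alt:
            raise GenerationError(f"ALT equals REF at {spec.chrom}:{spec.pos}")
        info = ";".join(
            f"{population_keys[pop]}={spec.af[pop]:.6g}"
            for pop in population_keys if pop in spec.af
        ) or "."
        lines.append(
            f"{spec.chrom}\t{spec.pos}\tsv{i}\t{ref}\t{spec.alt}\t.\tPASS\t{info}"
        )
    out_vcf = Path(out_vcf)
    out_vcf.write_text("\n".join(lines) + "\n")
    return out_vcf


def write_candidate_table(truth: pd.DataFrame, out_tsv, source: str = "synth") -> Path:
    """Render a plant_sites truth table in the unified candidate schema."""
    df = truth[["id", "chrom", "start", "end", "strand", "sequence"]].copy()
    df["end"] = df["start"] + df["sequence"].str.replace("-", "").str.len()
    df["source"] = source
    df["annotation"] = "unknown"
    df = df[CANDIDATE_COLUMNS]
    out_tsv = Path(out_tsv)
    df.to_csv(out_tsv, sep="\t", index=False)
    return out_tsv
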
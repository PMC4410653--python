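"""Tumor/normal two-pass simulation, read mixing and somatic-call validation.

The germline pass and the tumor pass share one seed, so the germline truth —
and hence the normal genome — is byte-identical between passes. The tumor
genome additionally carries the somatic set, minus any somatic variant whose
footprint collides with a germline footprint (dropped and reported, never
fatal). Normal contamination is modeled by mixing reads: each emitted pair is
drawn from the tumor pool with probability alpha (tumor purity), else the
normal pool, without replacement within each pool.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .diploid import DiploidGenome, build_diploid
from .sampling import (FootprintTracker, InsertionPool, SamplingSpec,
                       resolve_truth, sample_variants)
from .variants import Variant
from .varval import ComparisonResult, MatchParams, match_variants

log = logging.getLogger(__name__)

# fixed offsets keeping the somatic / mixing RNG streams off the germline ones
_SOMATIC_STREAM = 7919
_MIX_STREAM = 15485863


@dataclass(frozen=True)
class SomaticConfig:
    germline: SamplingSpec
    tumor_fraction: float = 0.3  # alpha: tumor purity of the mixed sample
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.tumor_fraction <= 1.0:
            raise ValueError("tumor_fraction must be in [0, 1]")


@dataclass
class SomaticPair:
    normal: DiploidGenome
    tumor: DiploidGenome
    germline_truth: list[Variant]
    somatic_truth: list[Variant]  # somatic variants actually applied
    dropped_somatic: list[Variant]  # collided with germline footprints


def _germline_truth(reference, db: Sequence[Variant], cfg: SomaticConfig,
                    pool: InsertionPool | None) -> list[Variant]:
    spec = replace(cfg.germline, seed=cfg.seed)
    sampled = sample_variants(db, spec, reference)
    rng = np.random.default_rng((cfg.seed, 1))
    return resolve_truth(sampled, pool, rng, reference)


def run_pair(reference, db: Sequence[Variant], somatic: Sequence[Variant],
             cfg: SomaticConfig, pool: InsertionPool | None = None) -> SomaticPair:
    """Run the germline pass twice — without and with the somatic set."""
    germline_normal = _germline_truth(reference, db, cfg, pool)
    germline_tumor = _germline_truth(reference, db, cfg, pool)
    assert germline_normal == germline_tumor, \
        "germline truth must be identical between passes under a shared seed"

    tracker = FootprintTracker(cfg.germline.min_gap)
    for v in germline_normal:
        tracker.add(v.chrom, *v.footprint)
    rng = np.random.default_rng((cfg.seed, _SOMATIC_STREAM))
    kept: list[Variant] = []
    dropped: list[Variant] = []
    for v in sorted(somatic, key=Variant.sort_key):
        s, e = v.footprint
        if tracker.accepts(v.chrom, s, e):
            tracker.add(v.chrom, s, e)
            kept.append(v)
        else:
            dropped.append(v)
    if dropped:
        log.warning("dropped %d somatic variants colliding with germline "
                    "footprints: %s", len(dropped),
                    ", ".join(v.id for v in dropped))
    kept = resolve_truth(kept, pool, rng, reference)

    normal = build_diploid(reference, germline_normal)
    tumor = build_diploid(reference, sorted(germline_tumor + kept,
                                            key=Variant.sort_key))
    return SomaticPair(normal, tumor, germline_normal, kept, dropped)


# ---------------------------------------------------------------------------
# Read mixing
# ---------------------------------------------------------------------------

def _load_pairs(fq1: str | Path, fq2: str | Path) -> list[tuple[str, str]]:
    def records(path):
        with open(path) as fh:
            lines = fh.read().splitlines()
        return ["\n".join(lines[i:i + 4]) + "\n" for i in range(0, len(lines), 4)]

    r1, r2 = records(fq1), records(fq2)
    if len(r1) != len(r2):
        raise ValueError("mate FASTQ files have different read counts")
    return list(zip(r1, r2))


@dataclass
class MixResult:
    n_pairs: int
    n_tumor: int
    fastq1: Path
    fastq2: Path

    @property
    def tumor_fraction(self) -> float:
        return self.n_tumor / self.n_pairs if self.n_pairs else 0.0


def mix_reads(normal_fq1, normal_fq2, tumor_fq1, tumor_fq2,
              alpha: float, n_pairs: int, seed: int,
              out_prefix: str | Path) -> MixResult:
    """Mix tumor and normal read pairs at tumor purity `alpha`.

    Pairs stay intact; origin is recoverable from the sample tag in the truth
    payload's read_id. Raises on pool exhaustion, stating the achievable
    maximum.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    normal = _load_pairs(normal_fq1, normal_fq2)
    tumor = _load_pairs(tumor_fq1, tumor_fq2)
    rng = np.random.default_rng((seed, _MIX_STREAM))
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    fq1_path = prefix.parent / (prefix.name + "_1.fq")
    fq2_path = prefix.parent / (prefix.name + "_2.fq")
    ni = ti = 0
    with open(fq1_path, "w") as f1, open(fq2_path, "w") as f2:
        for k in range(n_pairs):
            take_tumor = rng.random() < alpha
            if take_tumor and ti >= len(tumor):
                raise ValueError(
                    f"tumor pool exhausted after {k} pairs; at most "
                    f"~{len(tumor) + len(normal)} total pairs available")
            if not take_tumor and ni >= len(normal):
                raise ValueError(
                    f"normal pool exhausted after {k} pairs; at most "
                    f"~{len(tumor) + len(normal)} total pairs available")
            if take_tumor:
                r1, r2 = tumor[ti]
                ti += 1
            else:
                r1, r2 = normal[ni]
                ni += 1
            f1.write(r1)
            f2.write(r2)
    return MixResult(n_pairs, ti, fq1_path, fq2_path)


# ---------------------------------------------------------------------------
# Somatic call validation
# ---------------------------------------------------------------------------

@dataclass
class SomaticValidation:
    result: ComparisonResult
    germline_leaks: list[Variant]  # FP calls matching a germline truth variant


def validate_somatic(calls: Sequence[Variant], somatic_truth: Sequence[Variant],
                     germline_truth: Sequence[Variant],
                     params: MatchParams = MatchParams(),
                     reference=None) -> SomaticValidation:
    """Score somatic calls against somatic truth; flag FPs that are actually
    germline variants ("germline leaks"). Leaks remain FPs for precision."""
    result = match_variants(somatic_truth, calls, params, reference)
    leak_check = match_variants(germline_truth, result.fp, params)
    leaks = [call for _t, call in leak_check.tp]
    return SomaticValidation(result, leaks)
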
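"""Compare a caller's VCF against the truth set; report TPR/PPV/F1 stratified
by variant type and size bin.

Small variants (SNV/MNP and indels below the SV threshold) must match exactly
after canonical normalization. SVs match tolerantly: same type, breakpoint
start within ``bp_tolerance`` and reciprocal size ratio at least
``size_ratio_min`` (insertion content is not sequence-compared). Matching is
one-to-one and greedy in order of increasing breakpoint distance, ties broken
by larger size ratio then truth position; the test suite checks the greedy
matcher against an exhaustive optimal matcher on small fixtures.

Degenerate cells follow explicit conventions: PPV with zero calls is null
(not 1.0), TPR with zero truth is null; F1 is 0.0 when either input is 0 and
null when either is null, so empty cells never inflate summaries.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .variants import (DEFAULT_BINS, SizeBin, Variant, VarType, assign_bin,
                       normalize, validate_bins, variant_size)

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class MatchParams:
    sv_threshold: int = 50  # bp; at/above this size tolerant matching applies
    bp_tolerance: int = 100  # max breakpoint start distance for SV matching
    size_ratio_min: float = 0.8  # min(size)/max(size) lower bound
    require_genotype: bool = False

    def __post_init__(self):
        if self.sv_threshold < 1:
            raise ValueError("sv_threshold must be >= 1")
        if self.bp_tolerance < 0:
            raise ValueError("bp_tolerance must be >= 0")
        if not 0 < self.size_ratio_min <= 1:
            raise ValueError("size_ratio_min must be in (0, 1]")


@dataclass
class ComparisonResult:
    tp: list[tuple[Variant, Variant]]  # (truth, matched call)
    fn: list[Variant]  # unmatched truth
    fp: list[Variant]  # unmatched calls
    params: MatchParams


def f1(tpr: float | None, ppv: float | None) -> float | None:
    """Harmonic mean of sensitivity and precision.

    A zero input forces 0.0 (the harmonic-mean limit); otherwise a null
    (undefined) input propagates to null.
    """
    if tpr == 0 or ppv == 0:
        return 0.0
    if tpr is None or ppv is None:
        return None
    return 2 * tpr * ppv / (tpr + ppv)


def is_small(v: Variant, params: MatchParams) -> bool:
    if v.var_type in (VarType.SNV, VarType.MNP):
        return True
    return abs(v.svlen) < params.sv_threshold


def _small_key(v: Variant, params: MatchParams) -> tuple:
    key = (v.chrom, v.pos, v.var_type, v.ref_allele, v.alt_allele, v.svlen)
    if params.require_genotype:
        key += (tuple(sorted(v.genotype)),)
    return key


def _sv_pair_ok(t: Variant, c: Variant, p: MatchParams) -> tuple[int, float] | None:
    """Distance and size ratio if (truth, call) satisfy the SV match rule."""
    if t.var_type is not c.var_type or t.chrom != c.chrom:
        return None
    dist = abs(t.pos - c.pos)
    if dist > p.bp_tolerance:
        return None
    st, sc = abs(t.svlen), abs(c.svlen)
    ratio = min(st, sc) / max(st, sc)
    if ratio < p.size_ratio_min:
        return None
    return dist, ratio


def check_normalized(variants: Sequence[Variant], reference) -> None:
    """Pre-condition guard: every record must be a normalization fixed point."""
    for v in variants:
        if normalize(v, reference) != v:
            raise ValueError(f"variant {v.id} at {v.chrom}:{v.pos} is not "
                             "in canonical form; normalize inputs first")


def match_variants(truth: Sequence[Variant], calls: Sequence[Variant],
                   params: MatchParams = MatchParams(),
                   reference=None) -> ComparisonResult:
    """One-to-one matching of calls to truth; see module docstring for rules.

    Passing a reference enables the canonical-form pre-condition check.
    """
    if reference is not None:
        check_normalized(truth, reference)
        check_normalized(calls, reference)

    truth_small = [(i, v) for i, v in enumerate(truth) if is_small(v, params)]
    truth_sv = [(i, v) for i, v in enumerate(truth) if not is_small(v, params)]
    calls_small = [(j, c) for j, c in enumerate(calls) if is_small(c, params)]
    calls_sv = [(j, c) for j, c in enumerate(calls) if not is_small(c, params)]

    matched_truth: dict[int, int] = {}
    matched_call: set[int] = set()

    # exact matching for small variants
    index: dict[tuple, list[int]] = {}
    for j, c in calls_small:
        index.setdefault(_small_key(c, params), []).append(j)
    for i, v in truth_small:
        for j in index.get(_small_key(v, params), ()):
            if j not in matched_call:
                matched_truth[i] = j
                matched_call.add(j)
                break

    # tolerant matching for SVs: greedy by breakpoint distance, then
    # augmented to maximum cardinality so that a nearby-but-contested call
    # never strands a truth variant whose only partner it was
    candidates = []
    for i, t in truth_sv:
        for j, c in calls_sv:
            hit = _sv_pair_ok(t, c, params)
            if hit is not None:
                dist, ratio = hit
                candidates.append((dist, -ratio, t.pos, c.pos, i, j))
    candidates.sort()
    adj: dict[int, list[int]] = {}
    for _, _, _, _, i, j in candidates:
        adj.setdefault(i, []).append(j)
    call_owner: dict[int, int] = {}
    owned_truth: set[int] = set()
    for _, _, _, _, i, j in candidates:
        if i not in owned_truth and j not in call_owner:
            call_owner[j] = i
            owned_truth.add(i)

    def augment(i: int, visited: set[int]) -> bool:
        for j in adj.get(i, ()):  # preference order preserved
            if j in visited:
                continue
            visited.add(j)
            if j not in call_owner or augment(call_owner[j], visited):
                call_owner[j] = i
                return True
        return False

    matched_sv = set(call_owner.values())
    for i, _t in truth_sv:
        if i not in matched_sv and augment(i, set()):
            matched_sv = set(call_owner.values())
    for j, i in call_owner.items():
        matched_truth[i] = j
        matched_call.add(j)

    tp = [(truth[i], calls[j]) for i, j in sorted(matched_truth.items())]
    fn = [v for i, v in enumerate(truth) if i not in matched_truth]
    fp = [c for j, c in enumerate(calls) if j not in matched_call]
    return ComparisonResult(tp, fn, fp, params)


# ---------------------------------------------------------------------------
# Stratification
# ---------------------------------------------------------------------------

@dataclass
class Cell:
    tp: int = 0
    fn: int = 0
    fp: int = 0

    @property
    def tpr(self) -> float | None:
        n = self.tp + self.fn
        return self.tp / n if n else None

    @property
    def ppv(self) -> float | None:
        n = self.tp + self.fp
        return self.tp / n if n else None

    @property
    def f1(self) -> float | None:
        return f1(self.tpr, self.ppv)

    def to_dict(self) -> dict:
        return {"tp": self.tp, "fn": self.fn, "fp": self.fp,
                "tpr": self.tpr, "ppv": self.ppv, "f1": self.f1}


@dataclass
class StratifiedReport:
    bins: Sequence[SizeBin]
    cells: dict[tuple[str, str], Cell]  # (var_type, bin label) -> Cell
    by_type: dict[str, Cell]
    by_bin: dict[str, Cell]
    total: Cell
    params: MatchParams

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "params": {
                "sv_threshold": self.params.sv_threshold,
                "bp_tolerance": self.params.bp_tolerance,
                "size_ratio_min": self.params.size_ratio_min,
                "require_genotype": self.params.require_genotype,
            },
            "bins": [b.label for b in self.bins],
            "cells": [
                {"type": t, "bin": b, **cell.to_dict()}
                for (t, b), cell in sorted(self.cells.items())
            ],
            "by_type": {t: c.to_dict() for t, c in sorted(self.by_type.items())},
            "by_bin": {b: c.to_dict() for b, c in self.by_bin.items()},
            "total": self.total.to_dict(),
        }

    def write_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    def text_summary(self) -> str:
        def fmt(x):
            return "null" if x is None else f"{x:.4f}"

        lines = [f"{'type':6} {'bin':>10} {'tp':>6} {'fn':>6} {'fp':>6} "
                 f"{'tpr':>8} {'ppv':>8} {'f1':>8}"]
        for (t, b), c in sorted(self.cells.items()):
            lines.append(f"{t:6} {b:>10} {c.tp:>6} {c.fn:>6} {c.fp:>6} "
                         f"{fmt(c.tpr):>8} {fmt(c.ppv):>8} {fmt(c.f1):>8}")
        c = self.total
        lines.append(f"{'TOTAL':6} {'':>10} {c.tp:>6} {c.fn:>6} {c.fp:>6} "
                     f"{fmt(c.tpr):>8} {fmt(c.ppv):>8} {fmt(c.f1):>8}")
        return "\n".join(lines)


def stratify(result: ComparisonResult,
             bins: Sequence[SizeBin] = DEFAULT_BINS) -> StratifiedReport:
    """Tally TP/FN by truth type+size, FP by call type+size, with marginals."""
    validate_bins(bins)
    cells: dict[tuple[str, str], Cell] = {}
    by_type: dict[str, Cell] = {}
    by_bin: dict[str, Cell] = {}
    total = Cell()

    def bump(v: Variant, kind: str) -> None:
        t = v.var_type.value
        b = assign_bin(v, bins).label
        for cell in (cells.setdefault((t, b), Cell()),
                     by_type.setdefault(t, Cell()),
                     by_bin.setdefault(b, Cell()), total):
            setattr(cell, kind, getattr(cell, kind) + 1)

    for t, _c in result.tp:
        bump(t, "tp")
    for t in result.fn:
        bump(t, "fn")
    for c in result.fp:
        bump(c, "fp")
    return StratifiedReport(tuple(bins), cells, by_type, by_bin, total,
                            result.params)
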
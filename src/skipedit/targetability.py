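"""Genome-wide ABE-vs-BE3 targetability comparison.

Builds per-exon records of the best available guide under each editor and
derives (i) cumulative counts of targetable inner exons versus an
efficiency or off-target threshold and (ii) an overlap report comparing
the two editors on exons targetable by both.

Conditioning mirrors the two cumulative views: the efficiency curve
considers only guides passing the off-target cap (score <= ``ot_cap``,
default 10), while the off-target curve considers only guides with
on-target efficiency strictly above ``eff_floor`` (default 30 %).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .guide_design import (DEFAULT_EFFICIENCY_THRESHOLD,
                           DEFAULT_OFFTARGET_THRESHOLD, GuideCandidate)

MODES = ("ABE", "BE3")


@dataclass(frozen=True)
class ModeBest:
    """Conditional bests for one editor at one exon."""

    #: highest efficiency among guides with off-target score <= ot_cap
    best_efficiency: float | None
    #: lowest off-target score among guides with efficiency > eff_floor
    best_offtarget: float | None
    #: >=1 guide passes both thresholds simultaneously
    targetable: bool


@dataclass(frozen=True)
class TargetabilityRecord:
    exon_key: str
    abe: ModeBest
    be3: ModeBest

    def mode(self, mode: str) -> ModeBest:
        return self.abe if mode == "ABE" else self.be3


def _mode_best(cands: Sequence[GuideCandidate], eff_floor: float,
               ot_cap: float) -> ModeBest:
    effs = [c.predicted_efficiency for c in cands
            if c.offtarget_score is not None and c.offtarget_score <= ot_cap]
    ots = [c.offtarget_score for c in cands
           if c.predicted_efficiency > eff_floor and c.offtarget_score is not None]
    passing = any(
        c.predicted_efficiency > eff_floor
        and c.offtarget_score is not None and c.offtarget_score <= ot_cap
        for c in cands)
    return ModeBest(
        best_efficiency=max(effs) if effs else None,
        best_offtarget=min(ots) if ots else None,
        targetable=passing,
    )


def build_records(candidates: Iterable[GuideCandidate],
                  eff_floor: float = DEFAULT_EFFICIENCY_THRESHOLD,
                  ot_cap: float = DEFAULT_OFFTARGET_THRESHOLD) -> list[TargetabilityRecord]:
    """Group scored candidates (both modes mixed) into per-exon records."""
    by_exon: dict[str, dict[str, list[GuideCandidate]]] = {}
    for c in candidates:
        from .genome_io import format_exon_key
        key = c.exon_key if isinstance(c.exon_key, str) else format_exon_key(c.exon_key)
        by_exon.setdefault(key, {m: [] for m in MODES})[c.mode].append(c)
    records = []
    for key in sorted(by_exon):
        groups = by_exon[key]
        records.append(TargetabilityRecord(
            exon_key=key,
            abe=_mode_best(groups["ABE"], eff_floor, ot_cap),
            be3=_mode_best(groups["BE3"], eff_floor, ot_cap),
        ))
    return records


def cumulative_by_efficiency(records: Sequence[TargetabilityRecord],
                             grid: Sequence[float] | None = None) -> pd.DataFrame:
    """Exon counts with >=1 guide of efficiency >= threshold, per mode.

    Guides are pre-conditioned on the off-target cap used when building
    the records.  The curve is non-increasing in the threshold.
    """
    if grid is None:
        grid = np.arange(0.0, 101.0, 1.0)
    rows = []
    for t in grid:
        row = {"threshold": float(t)}
        for mode in MODES:
            row[f"{mode.lower()}_count"] = sum(
                1 for r in records
                if r.mode(mode).best_efficiency is not None
                and r.mode(mode).best_efficiency >= t)
        rows.append(row)
    return pd.DataFrame(rows)


def cumulative_by_offtarget(records: Sequence[TargetabilityRecord],
                            grid: Sequence[float] | None = None) -> pd.DataFrame:
    """Exon counts with >=1 guide of off-target score <= threshold, per mode.

    Guides are pre-conditioned on efficiency strictly above the floor used
    when building the records.  The curve is non-decreasing.
    """
    if grid is None:
        grid = np.arange(0.0, 20.5, 0.5)
    rows = []
    for x in grid:
        row = {"threshold": float(x)}
        for mode in MODES:
            row[f"{mode.lower()}_count"] = sum(
                1 for r in records
                if r.mode(mode).best_offtarget is not None
                and r.mode(mode).best_offtarget <= x)
        rows.append(row)
    return pd.DataFrame(rows)


def overlap_report(records: Sequence[TargetabilityRecord]) -> dict:
    """Compare editors on exons targetable by both.

    Among exons targetable by both ABE and BE3, counts where ABE's best
    efficiency is strictly higher (and strictly lower off-target score),
    with ties reported in their own buckets rather than assigned.
    """
    both = [r for r in records if r.abe.targetable and r.be3.targetable]
    abe_only = sum(1 for r in records if r.abe.targetable and not r.be3.targetable)
    be3_only = sum(1 for r in records if r.be3.targetable and not r.abe.targetable)
    neither = sum(1 for r in records if not r.abe.targetable and not r.be3.targetable)

    abe_higher_eff = sum(1 for r in both if r.abe.best_efficiency > r.be3.best_efficiency)
    be3_higher_eff = sum(1 for r in both if r.be3.best_efficiency > r.abe.best_efficiency)
    eff_ties = len(both) - abe_higher_eff - be3_higher_eff
    abe_lower_ot = sum(1 for r in both if r.abe.best_offtarget < r.be3.best_offtarget)
    be3_lower_ot = sum(1 for r in both if r.be3.best_offtarget < r.abe.best_offtarget)
    ot_ties = len(both) - abe_lower_ot - be3_lower_ot

    n_both = len(both)
    frac = lambda k: (k / n_both) if n_both else float("nan")  # noqa: E731
    return {
        "n_records": len(records),
        "both": n_both,
        "abe_only": abe_only,
        "be3_only": be3_only,
        "neither": neither,
        "abe_higher_eff": abe_higher_eff,
        "be3_higher_eff": be3_higher_eff,
        "eff_ties": eff_ties,
        "abe_higher_eff_frac": frac(abe_higher_eff),
        "abe_lower_ot": abe_lower_ot,
        "be3_lower_ot": be3_lower_ot,
        "ot_ties": ot_ties,
        "abe_lower_ot_frac": frac(abe_lower_ot),
    }


def plot_curves(eff_curve: pd.DataFrame, ot_curve: pd.DataFrame, out_prefix: str) -> None:
    """Optional cumulative-curve plots (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for curve, xlabel, name in (
            (eff_curve, "efficiency threshold (%)", "by_efficiency"),
            (ot_curve, "off-target score threshold", "by_offtarget")):
        fig, ax = plt.subplots(figsize=(5, 4))
        for mode in MODES:
            ax.plot(curve["threshold"], curve[f"{mode.lower()}_count"], label=mode)
        ax.set_xlabel(xlabel)
        ax.set_ylabel("targetable inner exons")
        ax.legend()
        fig.tight_layout()
        fig.savefig(f"{out_prefix}_{name}.png", dpi=120)
        plt.close(fig)
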
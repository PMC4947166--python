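"""Peptide-level differential HDX-MS analysis.

Hydrogen-deuterium exchange reports on backbone amide solvent exposure.
Given per-peptide deuterium uptake tables for two states (apo and holo),
this module computes relative fractional uptake (uptake / theoretically
exchangeable amides), the per-peptide summed uptake difference across the
exposure series, threshold-based classification of contiguous residue
regions with elevated exchange in either state, and a per-residue
projection for structure colouring.

The exchangeable-amide count follows the DynamX convention:
``len(sequence) - 1 - (prolines after the first residue)`` (the N-terminal
amide back-exchanges instantly and prolines have no amide hydrogen).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PeptideUptake",
    "UptakeTable",
    "DiffProfile",
    "Region",
    "max_exchangeable",
    "relative_fractional_uptake",
    "summed_difference",
    "classify_regions",
    "project_to_residues",
    "read_dynamx_csv",
]

STANDARD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class PeptideUptake:
    """Deuterium uptake of one peptic peptide over an exposure series.

    ``uptake`` has shape (n_timepoints, n_replicates), in Da.
    """

    sequence: str
    start: int  # 1-based inclusive
    end: int
    timepoints: np.ndarray  # minutes
    uptake: np.ndarray

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.uptake = np.atleast_2d(np.asarray(self.uptake, dtype=float))
        if self.end < self.start:
            raise ValueError("end must be >= start")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError("sequence length must match residue span")
        if self.uptake.shape[0] != self.timepoints.size:
            raise ValueError("uptake rows must match timepoints")
        if np.any(self.uptake < 0):
            raise ValueError("uptake must be non-negative")

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.sequence, self.start, self.end)

    def mean_uptake(self) -> np.ndarray:
        return self.uptake.mean(axis=1)


@dataclass
class UptakeTable:
    state: str
    peptides: list[PeptideUptake] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [p.key for p in self.peptides]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate peptide (sequence, start, end) keys")

    def by_key(self) -> dict[tuple[str, int, int], PeptideUptake]:
        return {p.key: p for p in self.peptides}


@dataclass
class Region:
    start: int
    end: int
    sign: int  # +1: more exchange in state A (apo); -1: more in state B (holo)
    mean_percent: float


@dataclass
class DiffProfile:
    """Per-peptide uptake differences (state A minus state B).

    ``table`` columns: sequence, start, end, summed_diff_da,
    rel_diff_percent, and one ``d_<t>min`` column per timepoint.
    """

    table: pd.DataFrame
    state_a: str
    state_b: str
    n_residues: int | None = None


def max_exchangeable(sequence: str) -> int:
    """Theoretically exchangeable backbone amides of a peptide."""
    if len(sequence) < 2:
        raise ValueError("sequence must have length >= 2")
    bad = set(sequence) - STANDARD_RESIDUES
    if bad:
        raise ValueError(f"non-standard residue(s): {sorted(bad)}")
    return len(sequence) - 1 - sequence[1:].count("P")


def relative_fractional_uptake(table: UptakeTable) -> pd.DataFrame:
    """Replicate-mean uptake divided by exchangeable amides, per timepoint.

    Returns a tidy frame (sequence, start, end, exposure_min, rfu).
    """
    rows = []
    for p in table.peptides:
        mx = max_exchangeable(p.sequence)
        if mx == 0:
            raise ValueError(f"peptide {p.key} has zero exchangeable amides")
        for t, u in zip(p.timepoints, p.mean_uptake()):
            rows.append((p.sequence, p.start, p.end, float(t), float(u) / mx))
    return pd.DataFrame(rows, columns=["sequence", "start", "end", "exposure_min", "rfu"])


def summed_difference(
    apo: UptakeTable, holo: UptakeTable, n_residues: int | None = None
) -> DiffProfile:
    """Per-peptide summed uptake difference (apo - holo) over all timepoints.

    Also expressed relative to the peptide's maximum possible summed uptake,
    as a percentage: 100 * sum_t(d_t) / (n_t * max_exchangeable).  Peptides
    present in only one table are dropped with a warning; rows are ordered
    N-terminus to C-terminus.
    """
    a, b = apo.by_key(), holo.by_key()
    shared = sorted(set(a) & set(b), key=lambda k: (k[1], k[2]))
    dropped = (set(a) | set(b)) - set(shared)
    if dropped:
        logger.warning("dropping %d unmatched peptide(s)", len(dropped))
    if not shared:
        raise ValueError("no shared peptides between states")
    rows = []
    tp_cols: list[str] = []
    for key in shared:
        pa, pb = a[key], b[key]
        if not np.array_equal(pa.timepoints, pb.timepoints):
            raise ValueError(f"timepoint mismatch for peptide {key}")
        d = pa.mean_uptake() - pb.mean_uptake()
        mx = max_exchangeable(pa.sequence)
        row = {
            "sequence": key[0],
            "start": key[1],
            "end": key[2],
            "summed_diff_da": float(d.sum()),
            "rel_diff_percent": 100.0 * float(d.sum()) / (d.size * mx),
        }
        tp_cols = []
        for t, dt in zip(pa.timepoints, d):
            col = f"d_{t:g}min"
            row[col] = float(dt)
            tp_cols.append(col)
        rows.append(row)
    cols = ["sequence", "start", "end", "summed_diff_da", "rel_diff_percent"] + tp_cols
    return DiffProfile(
        table=pd.DataFrame(rows, columns=cols),
        state_a=apo.state,
        state_b=holo.state,
        n_residues=n_residues,
    )


def project_to_residues(diff: DiffProfile) -> pd.DataFrame:
    """Project peptide relative differences onto residues.

    Each residue's value is the mean rel_diff_percent of all peptides
    covering it; uncovered residues get NaN.  The frame carries a
    ``coverage`` attribute (fraction of residues covered).
    """
    n = diff.n_residues or int(diff.table["end"].max())
    acc = np.zeros(n)
    cnt = np.zeros(n, dtype=int)
    for _, row in diff.table.iterrows():
        s, e = int(row["start"]), int(row["end"])
        acc[s - 1 : e] += row["rel_diff_percent"]
        cnt[s - 1 : e] += 1
    value = np.full(n, np.nan)
    covered = cnt > 0
    value[covered] = acc[covered] / cnt[covered]
    out = pd.DataFrame({"residue": np.arange(1, n + 1), "value": value, "n_peptides": cnt})
    out.attrs["coverage"] = float(covered.mean())
    return out


def classify_regions(diff: DiffProfile, threshold_percent: float = 5.0) -> list[Region]:
    """Maximal runs of residues with relative difference beyond +/- threshold.

    Positive regions have higher exchange in state A (apo-exposed); negative
    regions in state B (holo-exposed).  Uncovered residues break runs.
    """
    proj = project_to_residues(diff)
    values = proj["value"].to_numpy()
    signs = np.zeros(values.size, dtype=int)
    with np.errstate(invalid="ignore"):
        signs[values > threshold_percent] = 1
        signs[values < -threshold_percent] = -1
    regions: list[Region] = []
    i = 0
    while i < signs.size:
        if signs[i] == 0:
            i += 1
            continue
        j = i
        while j + 1 < signs.size and signs[j + 1] == signs[i]:
            j += 1
        regions.append(
            Region(
                start=i + 1,
                end=j + 1,
                sign=int(signs[i]),
                mean_percent=float(np.nanmean(values[i : j + 1])),
            )
        )
        i = j + 1
    return regions


def read_dynamx_csv(path, state: str, column_map: dict[str, str] | None = None) -> UptakeTable:
    """Read a DynamX-cluster-style CSV into an :class:`UptakeTable`.

    Expected columns (case-insensitive): state, sequence, start, end,
    exposure, uptake, replicate.  ``column_map`` renames other dialects onto
    these names.  ``exposure`` is in minutes.
    """
    df = pd.read_csv(path)
    df.columns = [str(c).strip().lower() for c in df.columns]
    if column_map:
        df = df.rename(columns={k.lower(): v.lower() for k, v in column_map.items()})
    required = {"state", "sequence", "start", "end", "exposure", "uptake"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing column(s): {sorted(missing)}")
    df = df[df["state"].astype(str) == state]
    if df.empty:
        raise ValueError(f"no rows for state {state!r}")
    if "replicate" not in df.columns:
        df = df.assign(replicate=1)
    peptides = []
    for (seq, start, end), grp in df.groupby(["sequence", "start", "end"], sort=True):
        tps = np.array(sorted(grp["exposure"].unique()), dtype=float)
        reps = sorted(grp["replicate"].unique())
        uptake = np.full((tps.size, len(reps)), np.nan)
        for _, r in grp.iterrows():
            ti = int(np.searchsorted(tps, float(r["exposure"])))
            uptake[ti, reps.index(r["replicate"])] = float(r["uptake"])
        if np.any(np.isnan(uptake)):
            raise ValueError(f"incomplete replicate grid for peptide {seq} {start}-{end}")
        peptides.append(
            PeptideUptake(sequence=str(seq), start=int(start), end=int(end), timepoints=tps, uptake=uptake)
        )
    return UptakeTable(state=state, peptides=peptides)
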
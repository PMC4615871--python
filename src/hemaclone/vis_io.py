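"""Ingestion of viral-integration-site (VIS) clone read-count tables.

The empirical unit of analysis is a long-format table with one row per clone
per sample — columns ``animal_id, cell_type, months, clone_id, reads`` —
accompanied by per-sample metadata ``animal_id, cell_type, months, S, f``
(total marked reads sequenced and marked fraction of blood).  From a sample
we build the clone-size histogram ``n_q`` (clones seen with exactly ``q``
reads), the rescaled relative frequency ``nu = f*q/S``, and the empirical
cumulative fraction ``Q(nu)`` of detected clones at or below ``nu`` — the
object whose time-invariance motivates fitting stationary distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom

from .steady_state import SizeDistribution

__all__ = ["CloneReadTable", "SizeHistogram", "load_clone_table",
           "write_clone_table", "histogram", "rescale_nu", "nu_min",
           "empirical_Q", "binomial_reference", "wide_to_long"]

TABLE_COLUMNS = ["animal_id", "cell_type", "months", "clone_id", "reads"]
META_COLUMNS = ["animal_id", "cell_type", "months", "S", "f"]
SAMPLE_KEY = ["animal_id", "cell_type", "months"]

# midpoint of the marked-fraction range typically reported for these
# experiments; used only when metadata lacks f, with a loud warning
DEFAULT_F = 0.065


@dataclass
class SizeHistogram:
    """Counts ``n_q`` of clones observed with exactly ``q`` reads in one sample."""

    q: np.ndarray
    n_q: np.ndarray
    S: int
    f: float
    animal_id: str = "sim"
    cell_type: str = "PBMC"
    months: float = 0.0

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=int)
        self.n_q = np.asarray(self.n_q, dtype=int)
        if self.q.size != self.n_q.size:
            raise ValueError("q and n_q must have equal length")
        if np.any(self.q < 1):
            raise ValueError("detected clones have at least one read")
        if np.any(self.n_q < 1):
            raise ValueError("listed read counts must have n_q >= 1")
        order = np.argsort(self.q)
        self.q = self.q[order]
        self.n_q = self.n_q[order]

    @property
    def n_clones(self) -> int:
        """Number of distinct detected clones (realized C_s)."""
        return int(self.n_q.sum())

    @property
    def total_reads(self) -> int:
        return int(np.dot(self.q, self.n_q))

    def expand(self) -> np.ndarray:
        """Per-clone read counts (one entry per clone)."""
        return np.repeat(self.q, self.n_q)

    def to_tsv(self, path) -> None:
        pd.DataFrame({"q": self.q, "n_q": self.n_q}).to_csv(
            path, sep="\t", index=False)


@dataclass
class CloneReadTable:
    """Validated long-format clone read-count table plus per-sample metadata."""

    data: pd.DataFrame
    metadata: pd.DataFrame

    def samples(self) -> pd.DataFrame:
        return self.metadata[SAMPLE_KEY].drop_duplicates()

    def select(self, animal_id: str, cell_type: str, months: float) -> pd.DataFrame:
        d = self.data
        return d[(d.animal_id == animal_id) & (d.cell_type == cell_type)
                 & (np.isclose(d.months, months))]


def _validate(data: pd.DataFrame, metadata: pd.DataFrame) -> None:
    problems = []
    for i, row in data.iterrows():
        if row["reads"] < 1:
            problems.append(f"line {i + 2}: reads must be >= 1 (got {row['reads']})")
    dup = data.duplicated(subset=SAMPLE_KEY + ["clone_id"])
    for i in data.index[dup]:
        problems.append(f"line {i + 2}: duplicate clone row")
    have_meta = set(map(tuple, metadata[SAMPLE_KEY].itertuples(index=False)))
    for key, grp in data.groupby(SAMPLE_KEY):
        if key not in have_meta:
            problems.append(f"sample {key}: missing metadata row")
        else:
            S = metadata.set_index(SAMPLE_KEY).loc[key, "S"]
            if grp["reads"].sum() > S:
                problems.append(
                    f"sample {key}: clone reads sum to {grp['reads'].sum()} > S={S}")
    if problems:
        raise ValueError("invalid clone table:\n" + "\n".join(problems))


def load_clone_table(path, metadata_path) -> CloneReadTable:
    """Load and validate a TSV clone table with its per-sample metadata.

    Rows violating the invariants (reads < 1, duplicate clones, missing
    metadata, reads exceeding S) are reported with line numbers.
    """
    data = pd.read_csv(path, sep="\t")
    if data.empty:
        raise ValueError(f"{path}: no data rows")
    missing = set(TABLE_COLUMNS) - set(data.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    meta = pd.read_csv(metadata_path, sep="\t")
    missing = set(META_COLUMNS) - {*meta.columns, "f"}
    if missing - {"f"}:
        raise ValueError(f"{metadata_path}: missing columns {sorted(missing)}")
    if "f" not in meta.columns or meta["f"].isna().any():
        warnings.warn(
            f"metadata lacks the marked fraction f for some samples; "
            f"defaulting to f={DEFAULT_F} (midpoint of the typical 0.03-0.1 "
            "range). Rescaled frequencies nu will inherit this assumption.",
            stacklevel=2)
        if "f" not in meta.columns:
            meta["f"] = DEFAULT_F
        meta["f"] = meta["f"].fillna(DEFAULT_F)
    data = data[TABLE_COLUMNS]
    _validate(data, meta)
    return CloneReadTable(data=data.reset_index(drop=True), metadata=meta)


def write_clone_table(table: CloneReadTable, path, metadata_path) -> None:
    table.data.to_csv(path, sep="\t", index=False)
    table.metadata.to_csv(metadata_path, sep="\t", index=False)


def histogram(table: CloneReadTable, animal_id: str, cell_type: str,
              months: float) -> SizeHistogram:
    """Clone-size histogram of one sample: n_q = #clones with exactly q reads."""
    rows = table.select(animal_id, cell_type, months)
    if rows.empty:
        raise ValueError(
            f"no sample ({animal_id}, {cell_type}, {months}) in table")
    meta = table.metadata
    m = meta[(meta.animal_id == animal_id) & (meta.cell_type == cell_type)
             & (np.isclose(meta.months, months))].iloc[0]
    q, n_q = np.unique(rows["reads"].to_numpy(), return_counts=True)
    return SizeHistogram(q=q, n_q=n_q, S=int(m["S"]), f=float(m["f"]),
                         animal_id=animal_id, cell_type=cell_type,
                         months=float(months))


def rescale_nu(q, S: int, f: float):
    """Relative clone frequency in blood: nu = f*q/S."""
    q = np.asarray(q)
    if np.any(q < 1) or np.any(q > S):
        raise ValueError("require 1 <= q <= S")
    if not 0.0 < f <= 1.0:
        raise ValueError("f must lie in (0, 1]")
    return f * q / S


def nu_min(S: int, f: float) -> float:
    """Minimum detectable relative frequency, nu_min = f/S (a single read)."""
    return f / S


def empirical_Q(hist: SizeHistogram) -> tuple[np.ndarray, np.ndarray]:
    """Right-continuous step function Q(nu): fraction of detected clones with
    rescaled frequency at or below nu.  Ties in nu accumulate in one step."""
    if hist.n_clones == 0:
        raise ValueError("empty histogram")
    nu = rescale_nu(hist.q, max(hist.S, int(hist.q.max())), hist.f)
    Q = np.cumsum(hist.n_q) / hist.n_clones
    return nu, Q


def eval_step_Q(nu_grid, nu: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Evaluate a right-continuous Q step function on arbitrary nu values."""
    idx = np.searchsorted(nu, nu_grid, side="right") - 1
    out = np.where(idx >= 0, Q[np.clip(idx, 0, Q.size - 1)], 0.0)
    return out


def binomial_reference(S: int, mean_size: float) -> SizeDistribution:
    """Binomial(S, mean_size/S) clone-size law used as the overlay reference.

    A sample of fixed depth S in which every clone had identical underlying
    frequency would show binomial read counts; real and modeled distributions
    carry far more mass at small sizes than this reference.
    """
    if mean_size > S:
        raise ValueError("mean_size must not exceed S")
    values = binom.pmf(np.arange(S + 1), S, mean_size / S)
    return SizeDistribution(values, truncated_mass=0.0, kind="binomial-ref")


def wide_to_long(wide: pd.DataFrame, animal_id: str, cell_type: str) -> pd.DataFrame:
    """Convert a wide clone x timepoint read matrix (index clone_id, columns
    months) to the long/tidy layout used throughout."""
    long = wide.stack().rename("reads").reset_index()
    long.columns = ["clone_id", "months", "reads"]
    long = long[long.reads >= 1].copy()
    long["animal_id"] = animal_id
    long["cell_type"] = cell_type
    long["months"] = long["months"].astype(float)
    return long[TABLE_COLUMNS].reset_index(drop=True)
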
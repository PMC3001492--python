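"""Spot-table ingestion and per-array M/A computation.

Reads GenePix-style tab-delimited result tables (one row per printed spot,
median foreground/background intensities for the red Cy5 and green Cy3
channels plus an integer quality flag), drops control spots, and turns each
array into one column of an :class:`MASet`:

    M = log2(R / G)          the within-spot log ratio
    A = (log2 R + log2 G)/2  the average log intensity

Flagged spots (negative GenePix flag: high local background, aberrant spot
shape, not found) are kept but down-weighted to 0.1 so they influence the
downstream weighted fits 10x less.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError

FLAGGED_WEIGHT = 0.1


@dataclass(frozen=True)
class SpotDialect:
    """Column naming of a spot table; defaults follow GenePix Pro exports."""

    id_col: str = "ID"
    flag_col: str = "Flags"
    f_red_col: str = "F635 Median"
    b_red_col: str = "B635 Median"
    f_green_col: str = "F532 Median"
    b_green_col: str = "B532 Median"
    comment_prefix: str = "#"
    control_pattern: str = r"(?i)^(control|empty|blank|buffer|corner|spike)"

    @property
    def required(self) -> tuple[str, ...]:
        return (
            self.id_col,
            self.flag_col,
            self.f_red_col,
            self.b_red_col,
            self.f_green_col,
            self.b_green_col,
        )


@dataclass(frozen=True)
class SpotRecord:
    probe_id: str
    flag: int
    f_red_median: float
    b_red_median: float
    f_green_median: float
    b_green_median: float


def read_spot_table(path, dialect: SpotDialect | None = None) -> list[SpotRecord]:
    """Read one array's spot table; control spots are removed."""
    dialect = dialect or SpotDialect()
    df = pd.read_csv(path, sep="\t", comment=dialect.comment_prefix or None, dtype=str)
    for col in dialect.required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if dialect.control_pattern:
        ctrl = df[dialect.id_col].str.match(dialect.control_pattern)
        df = df[~ctrl.fillna(False)]
    ids = df[dialect.id_col]
    dup = ids[ids.duplicated()]
    if len(dup):
        raise FormatError(
            f"{path}: duplicate probe id {dup.iloc[0]!r} (probes are printed in singlets)"
        )
    cols = [
        df[c].to_numpy()
        for c in (
            dialect.id_col,
            dialect.flag_col,
            dialect.f_red_col,
            dialect.b_red_col,
            dialect.f_green_col,
            dialect.b_green_col,
        )
    ]
    return [
        SpotRecord(pid, int(float(fl)), float(fr), float(br), float(fg), float(bg))
        for pid, fl, fr, br, fg, bg in zip(*cols)
    ]


def write_spot_table(records: list[SpotRecord], path, dialect: SpotDialect | None = None) -> None:
    dialect = dialect or SpotDialect()
    with open(path, "w") as fh:
        fh.write("\t".join(dialect.required) + "\n")
        for r in records:
            vals = (
                r.probe_id,
                str(r.flag),
                _fmt(r.f_red_median),
                _fmt(r.b_red_median),
                _fmt(r.f_green_median),
                _fmt(r.b_green_median),
            )
            fh.write("\t".join(vals) + "\n")


def _fmt(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else f"{x:.17g}"


def compute_ma(
    records: list[SpotRecord],
    probes: list[str] | None = None,
    background_policy: str = "none",
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """M, A and spot weights for one array.

    background_policy "none" uses the foreground medians as-is (default);
    "subtract" uses foreground - local background, and any spot whose signal
    becomes non-positive gets weight 0 with M/A missing rather than raising.

    Returns (M, A, W, probes) aligned to `probes` (defaults to the record
    order); probes absent from the array get weight 0.
    """
    if background_policy not in ("none", "subtract"):
        raise ValueError(f"unknown background policy {background_policy!r}")
    if probes is None:
        probes = [r.probe_id for r in records]
    n = len(probes)
    M = np.full(n, np.nan)
    A = np.full(n, np.nan)
    W = np.zeros(n)
    index = {p: i for i, p in enumerate(probes)}
    for rec in records:
        i = index.get(rec.probe_id)
        if i is None:
            continue
        r, g = rec.f_red_median, rec.f_green_median
        if background_policy == "subtract":
            r -= rec.b_red_median
            g -= rec.b_green_median
        if r <= 0 or g <= 0:
            continue  # weight stays 0, M/A stay missing
        lr, lg = np.log2(r), np.log2(g)
        M[i] = lr - lg
        A[i] = (lr + lg) / 2.0
        W[i] = FLAGGED_WEIGHT if rec.flag < 0 else 1.0
    return M, A, W, list(probes)


@dataclass
class MASet:
    """Per-probe, per-array M (log ratio), A (log intensity) and spot weights."""

    probes: list[str]
    arrays: list[str]
    M: np.ndarray  # probes x arrays
    A: np.ndarray
    W: np.ndarray  # in {0, 0.1, 1} under the default flag policy

    def __post_init__(self) -> None:
        shape = (len(self.probes), len(self.arrays))
        for name in ("M", "A", "W"):
            mat = np.asarray(getattr(self, name), dtype=float)
            if mat.shape != shape:
                raise FormatError(
                    f"{name} matrix has shape {mat.shape}, expected {shape}"
                )
            setattr(self, name, mat)

    def subset_arrays(self, array_ids: list[str]) -> "MASet":
        pos = [self.arrays.index(a) for a in array_ids]
        return MASet(
            probes=list(self.probes),
            arrays=list(array_ids),
            M=self.M[:, pos],
            A=self.A[:, pos],
            W=self.W[:, pos],
        )

    # -- serialization: three TSV matrices, probe rows x array columns ---
    def write(self, directory, prefix: str = "maset") -> None:
        for name in ("M", "A", "W"):
            df = pd.DataFrame(getattr(self, name), index=self.probes, columns=self.arrays)
            df.index.name = "probe_id"
            df.to_csv(f"{directory}/{prefix}_{name}.tsv", sep="\t", float_format="%.10g")

    @classmethod
    def read(cls, directory, prefix: str = "maset") -> "MASet":
        mats = {}
        for name in ("M", "A", "W"):
            df = pd.read_csv(f"{directory}/{prefix}_{name}.tsv", sep="\t", index_col=0)
            mats[name] = df
        m = mats["M"]
        return cls(
            probes=[str(p) for p in m.index],
            arrays=[str(c) for c in m.columns],
            M=mats["M"].to_numpy(float),
            A=mats["A"].to_numpy(float),
            W=mats["W"].to_numpy(float),
        )


def maset_from_tables(
    spot_tables: dict[str, list[SpotRecord]],
    array_order: list[str] | None = None,
    background_policy: str = "none",
) -> MASet:
    """Assemble an MASet from per-array spot records keyed by array id."""
    arrays = array_order or list(spot_tables)
    probes: list[str] = []
    seen = set()
    for aid in arrays:
        for rec in spot_tables[aid]:
            if rec.probe_id not in seen:
                seen.add(rec.probe_id)
                probes.append(rec.probe_id)
    cols = [compute_ma(spot_tables[a], probes, background_policy) for a in arrays]
    return MASet(
        probes=probes,
        arrays=list(arrays),
        M=np.column_stack([c[0] for c in cols]),
        A=np.column_stack([c[1] for c in cols]),
        W=np.column_stack([c[2] for c in cols]),
    )
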
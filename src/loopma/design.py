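"""Looped, dye-swapped two-colour hybridization designs.

A two-colour array compares two mRNA samples directly on one slide, one
labelled with Cy3 (green) and one with Cy5 (red).  A *loop design* chains
time points into a cycle (each array hybridizes two successive samples,
every edge repeated with the dyes swapped), and a *round robin* hybridizes
every pair of samples in both dye orientations.  Bridge arrays connect two
such series so that all samples become jointly estimable on one graph.

The design used throughout this package is the 32-array study layout:
an 8-point proepicardium (PE) explant time course (0, 14, 24, 36, 48, 60,
72 and 120 h in culture; the 0 h sample is the HH16 embryo before
explanting) hybridized as a dye-swapped loop (16 arrays, 4 technical
replicates per time point), a 4-stage epicardium (Epi) series (HH25, HH29,
HH32, HH37) hybridized as a dye-swapped round robin (12 arrays, 6
replicates per stage), and two dye-swapped bridges tying Epi HH25 and Epi
HH29 to the PE explant at 48 h (4 arrays).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DesignError

PE_TIMES_H = (0.0, 14.0, 24.0, 36.0, 48.0, 60.0, 72.0, 120.0)
EPI_STAGES = ("HH25", "HH29", "HH32", "HH37")


@dataclass(frozen=True)
class Sample:
    """One labelled mRNA sample: a PE time point or an Epi stage."""

    id: str
    series: str  # "PE" or "EPI"
    time_h: float | None = None  # PE only; 0 h for the HH16 pre-explant sample
    stage: str | None = None

    def __post_init__(self) -> None:
        if self.series not in ("PE", "EPI"):
            raise DesignError(f"unknown series {self.series!r} for sample {self.id!r}")
        if self.series == "PE" and self.time_h is None:
            raise DesignError(f"PE sample {self.id!r} must carry a time")
        if self.series == "EPI" and self.stage is None:
            raise DesignError(f"Epi sample {self.id!r} must carry a stage")


@dataclass(frozen=True)
class ArrayHyb:
    """One hybridization: a Cy3-labelled and a Cy5-labelled sample on one slide."""

    array_id: str
    cy3_sample: str
    cy5_sample: str

    def __post_init__(self) -> None:
        if self.cy3_sample == self.cy5_sample:
            raise DesignError(
                f"array {self.array_id!r} hybridizes sample {self.cy3_sample!r} "
                "against itself"
            )


@dataclass
class DesignGraph:
    """Samples as nodes, arrays as dye-directed edges."""

    samples: list[Sample] = field(default_factory=list)
    arrays: list[ArrayHyb] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise DesignError("duplicate sample ids in design")
        aids = [a.array_id for a in self.arrays]
        if len(set(aids)) != len(aids):
            raise DesignError("duplicate array ids in design")
        known = set(ids)
        for a in self.arrays:
            for sid in (a.cy3_sample, a.cy5_sample):
                if sid not in known:
                    raise DesignError(
                        f"array {a.array_id!r} references unknown sample {sid!r}"
                    )

    # -- lookup helpers -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return [s.id for s in self.samples]

    @property
    def array_ids(self) -> list[str]:
        return [a.array_id for a in self.arrays]

    def sample(self, sample_id: str) -> Sample:
        for s in self.samples:
            if s.id == sample_id:
                return s
        raise DesignError(f"unknown sample {sample_id!r}")

    def arrays_for_sample(self, sample_id: str) -> list[ArrayHyb]:
        return [
            a
            for a in self.arrays
            if sample_id in (a.cy3_sample, a.cy5_sample)
        ]

    def subgraph(self, series: str) -> "DesignGraph":
        """Arrays whose both samples belong to `series`, with those samples."""
        keep = {s.id for s in self.samples if s.series == series}
        arrays = [
            a for a in self.arrays if a.cy3_sample in keep and a.cy5_sample in keep
        ]
        samples = [s for s in self.samples if s.id in keep]
        return DesignGraph(samples=samples, arrays=arrays)

    # -- linear-model building blocks -----------------------------------
    def incidence_matrix(self) -> np.ndarray:
        """Arrays x samples matrix with +1 at each array's Cy5 sample, -1 at Cy3.

        The per-spot log ratio M = log2(Cy5/Cy3) has expectation
        e[cy5] - e[cy3] (+ dye terms), so this is the design matrix of the
        sample effects in ratio space.
        """
        idx = {s.id: j for j, s in enumerate(self.samples)}
        X = np.zeros((len(self.arrays), len(self.samples)))
        for i, a in enumerate(self.arrays):
            X[i, idx[a.cy5_sample]] = 1.0
            X[i, idx[a.cy3_sample]] = -1.0
        return X

    def effect_design_matrix(self, reference: str) -> tuple[np.ndarray, list[str]]:
        """Incidence with the reference column dropped, plus a constant dye column.

        Returns (arrays x ((n_samples - 1) + 1) matrix, column names); the last
        column is the dye/offset term.
        """
        if reference not in self.sample_ids:
            raise DesignError(f"reference sample {reference!r} not in design")
        X = self.incidence_matrix()
        cols = [sid for sid in self.sample_ids if sid != reference]
        keep = [j for j, sid in enumerate(self.sample_ids) if sid != reference]
        Xr = np.column_stack([X[:, keep], np.ones(len(self.arrays))])
        return Xr, cols + ["dye"]

    def is_connected(self) -> bool:
        if not self.samples:
            return True
        adj: dict[str, set[str]] = {s.id: set() for s in self.samples}
        for a in self.arrays:
            adj[a.cy3_sample].add(a.cy5_sample)
            adj[a.cy5_sample].add(a.cy3_sample)
        seen = {self.samples[0].id}
        stack = [self.samples[0].id]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return len(seen) == len(self.samples)


@dataclass
class ValidationReport:
    connected: bool
    dye_imbalance: dict[str, int]  # per sample: |#Cy5 - #Cy3|
    design_rank: int
    required_rank: int

    @property
    def estimable(self) -> bool:
        return self.design_rank == self.required_rank

    @property
    def dye_balanced(self) -> bool:
        return all(v == 0 for v in self.dye_imbalance.values())

    @property
    def ok(self) -> bool:
        # dye balance is reported but not fatal: bridge arrays cannot be
        # balanced against every partner in the study design itself
        return self.connected and self.estimable


def _pair_arrays(s_cy3: Sample, s_cy5: Sample, tag: str = "") -> tuple[ArrayHyb, ArrayHyb]:
    base = f"{s_cy3.id}__{s_cy5.id}{tag}"
    return (
        ArrayHyb(f"{base}_a", cy3_sample=s_cy3.id, cy5_sample=s_cy5.id),
        ArrayHyb(f"{base}_b", cy3_sample=s_cy5.id, cy5_sample=s_cy3.id),
    )


def build_pe_loop(samples: list[Sample]) -> DesignGraph:
    """Cyclic loop over temporally ordered samples, every edge dye-swapped.

    n samples -> 2n arrays; every sample sits on exactly 4 arrays
    (both orientations of the edge to its predecessor and to its successor).
    """
    n = len(samples)
    if n < 2:
        raise DesignError("a loop needs at least 2 samples")
    arrays: list[ArrayHyb] = []
    for i in range(n):
        a, b = _pair_arrays(samples[i], samples[(i + 1) % n])
        arrays.extend([a, b])
    return DesignGraph(samples=list(samples), arrays=arrays)


def build_round_robin(samples: list[Sample]) -> DesignGraph:
    """Every unordered pair hybridized in both dye orientations.

    n samples -> n(n-1) arrays; every sample sits on 2(n-1) arrays.
    """
    n = len(samples)
    if n < 2:
        raise DesignError("a round robin needs at least 2 samples")
    arrays: list[ArrayHyb] = []
    for i in range(n):
        for j in range(i + 1, n):
            a, b = _pair_arrays(samples[i], samples[j])
            arrays.extend([a, b])
    return DesignGraph(samples=list(samples), arrays=arrays)


def connect_series(
    g1: DesignGraph, g2: DesignGraph, bridges: list[tuple[str, str]]
) -> DesignGraph:
    """Merge two designs and add a dye-swapped array pair per bridge."""
    samples = list(g1.samples) + [s for s in g2.samples if s.id not in set(g1.sample_ids)]
    lookup = {s.id: s for s in samples}
    arrays = list(g1.arrays) + list(g2.arrays)
    for sid_a, sid_b in bridges:
        for sid in (sid_a, sid_b):
            if sid not in lookup:
                raise DesignError(f"bridge references unknown sample {sid!r}")
        a, b = _pair_arrays(lookup[sid_a], lookup[sid_b])
        arrays.extend([a, b])
    return DesignGraph(samples=samples, arrays=arrays)


def validate_design(g: DesignGraph, reference: str | None = None) -> ValidationReport:
    """Connectivity, per-sample dye balance, and estimability of sample+dye effects."""
    imbalance: dict[str, int] = {}
    for s in g.samples:
        n5 = sum(1 for a in g.arrays if a.cy5_sample == s.id)
        n3 = sum(1 for a in g.arrays if a.cy3_sample == s.id)
        imbalance[s.id] = abs(n5 - n3)
    ref = reference or (g.samples[0].id if g.samples else "")
    required = max(len(g.samples) - 1, 0) + 1
    if g.arrays and g.samples:
        X, _ = g.effect_design_matrix(ref)
        rank = int(np.linalg.matrix_rank(X))
    else:
        rank = 0
    return ValidationReport(
        connected=g.is_connected(),
        dye_imbalance=imbalance,
        design_rank=rank,
        required_rank=required,
    )


# ----------------------------------------------------------------------
# The study design
# ----------------------------------------------------------------------

def pe_samples() -> list[Sample]:
    out = []
    for t in PE_TIMES_H:
        stage = "HH16" if t == 0 else None
        out.append(Sample(id=f"PE_{int(t):03d}h", series="PE", time_h=t, stage=stage))
    return out


def epi_samples() -> list[Sample]:
    return [Sample(id=f"EPI_{st}", series="EPI", stage=st) for st in EPI_STAGES]


def study_design() -> DesignGraph:
    """The full 32-array design: PE loop + Epi round robin + 2 dye-swapped bridges."""
    pe = build_pe_loop(pe_samples())
    epi = build_round_robin(epi_samples())
    return connect_series(
        pe, epi, bridges=[("EPI_HH25", "PE_048h"), ("EPI_HH29", "PE_048h")]
    )


# ----------------------------------------------------------------------
# On-disk tables
# ----------------------------------------------------------------------

def _fmt_time(t: float | None) -> str:
    if t is None:
        return ""
    return str(int(t)) if float(t).is_integer() else repr(float(t))


def write_design_tables(g: DesignGraph, array_path, sample_path) -> None:
    """Write the array and sample tables as tab-delimited text (diff-stable)."""
    with open(array_path, "w") as fh:
        fh.write("array_id\tcy3_sample\tcy5_sample\n")
        for a in g.arrays:
            fh.write(f"{a.array_id}\t{a.cy3_sample}\t{a.cy5_sample}\n")
    with open(sample_path, "w") as fh:
        fh.write("sample_id\tseries\ttime_h\tstage\n")
        for s in g.samples:
            fh.write(f"{s.id}\t{s.series}\t{_fmt_time(s.time_h)}\t{s.stage or ''}\n")


def read_design_tables(array_path, sample_path) -> DesignGraph:
    sdf = pd.read_csv(sample_path, sep="\t", dtype=str, keep_default_na=False)
    samples = [
        Sample(
            id=r["sample_id"],
            series=r["series"],
            time_h=float(r["time_h"]) if r["time_h"] != "" else None,
            stage=r["stage"] or None,
        )
        for _, r in sdf.iterrows()
    ]
    adf = pd.read_csv(array_path, sep="\t", dtype=str, keep_default_na=False)
    arrays = [
        ArrayHyb(r["array_id"], cy3_sample=r["cy3_sample"], cy5_sample=r["cy5_sample"])
        for _, r in adf.iterrows()
    ]
    return DesignGraph(samples=samples, arrays=arrays)
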
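"""Data model and I/O for targeted-metabolomics peak-area tables.

The central object is :class:`MetabolomicsDataset`: a samples-by-metabolites
matrix of non-negative MRM peak areas with per-sample metadata (subject,
group, fluid, replicate).  Missing cells are stored as NaN.  The processing
order used by the pipeline is fixed: replicates are averaged on the raw area
scale first, then the natural logarithm is taken, then low-detection
metabolites are filtered, and finally subject-matched plasma/CSF profiles are
assembled into a :class:`PairedProfileTable`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from crossfluid.errors import (
    EmptyResultError,
    FormatError,
    IntegrityError,
    ParameterError,
)

log = logging.getLogger(__name__)

GROUPS = ("glioma", "control")
FLUIDS = ("plasma", "csf")

REQUIRED_COLUMNS = ("subject", "group", "fluid", "replicate", "metabolite", "peak_area")


@dataclass(frozen=True, order=True)
class SampleKey:
    """Identity of one measured profile: subject, clinical group, fluid, replicate."""

    subject_id: str
    group: str
    fluid: str
    replicate: int

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ParameterError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.fluid not in FLUIDS:
            raise ParameterError(f"unknown fluid {self.fluid!r}; expected one of {FLUIDS}")
        if self.replicate < 1:
            raise ParameterError(f"replicate index must be >= 1, got {self.replicate}")


@dataclass
class MetabolomicsDataset:
    """Peak-area matrix [samples x metabolites] with sample metadata.

    ``peak_area`` holds non-negative floats; missing values are NaN.
    """

    samples: list[SampleKey]
    metabolites: list[str]
    peak_area: np.ndarray

    def __post_init__(self) -> None:
        self.peak_area = np.asarray(self.peak_area, dtype=float)
        if self.peak_area.shape != (len(self.samples), len(self.metabolites)):
            raise IntegrityError(
                f"peak_area shape {self.peak_area.shape} does not match "
                f"{len(self.samples)} samples x {len(self.metabolites)} metabolites"
            )
        if len(set(self.metabolites)) != len(self.metabolites):
            dupes = sorted({m for m in self.metabolites if self.metabolites.count(m) > 1})
            raise IntegrityError(f"duplicate metabolite IDs: {dupes}")
        keys = [(s.subject_id, s.fluid, s.replicate) for s in self.samples]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise IntegrityError(f"duplicate (subject, fluid, replicate) keys: {dupes}")
        group_of: dict[str, str] = {}
        for s in self.samples:
            if group_of.setdefault(s.subject_id, s.group) != s.group:
                raise IntegrityError(f"subject {s.subject_id!r} assigned to more than one group")
        present = np.isfinite(self.peak_area)
        if np.any(self.peak_area[present] < 0):
            raise IntegrityError("peak_area contains negative values")

    # -- convenience views -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean matrix, True where the cell is missing."""
        return ~np.isfinite(self.peak_area)

    @property
    def subjects(self) -> list[str]:
        """Unique subject IDs in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.subject_id, None)
        return list(seen)

    def group_of(self, subject_id: str) -> str:
        for s in self.samples:
            if s.subject_id == subject_id:
                return s.group
        raise KeyError(subject_id)

    def sample_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject": [s.subject_id for s in self.samples],
                "group": [s.group for s in self.samples],
                "fluid": [s.fluid for s in self.samples],
                "replicate": [s.replicate for s in self.samples],
            }
        )

    def to_long(self) -> pd.DataFrame:
        """Long-format view with one row per (sample, metabolite) cell."""
        meta = self.sample_table()
        frames = []
        for j, m in enumerate(self.metabolites):
            f = meta.copy()
            f["metabolite"] = m
            f["peak_area"] = self.peak_area[:, j]
            frames.append(f)
        return pd.concat(frames, ignore_index=True)


def read_peak_table(path, sep: str | None = None) -> MetabolomicsDataset:
    """Read a long-format delimited peak table into a dataset.

    Required columns: subject, group, fluid, replicate, metabolite, peak_area.
    Unparseable peak_area entries become missing cells.  Duplicate
    (sample, metabolite) rows raise :class:`IntegrityError`.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c", dtype=str)
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"missing required columns {missing_cols} in {path}")
    df = df.copy()

    def _to_float(v):  # Python float() is correctly rounded; pandas' parser is not
        try:
            return float(v)
        except (TypeError, ValueError):
            return np.nan

    df["peak_area"] = df["peak_area"].map(_to_float)
    df["replicate"] = pd.to_numeric(df["replicate"], errors="raise").astype(int)

    key_cols = ["subject", "fluid", "replicate", "metabolite"]
    dup = df.duplicated(subset=key_cols, keep=False)
    if dup.any():
        first = df.loc[dup, key_cols].iloc[0].tolist()
        raise IntegrityError(f"duplicate (sample, metabolite) row for key {tuple(first)}")

    sample_cols = ["subject", "group", "fluid", "replicate"]
    sample_meta = df[sample_cols].drop_duplicates(subset=["subject", "fluid", "replicate"])
    samples = [
        SampleKey(str(r.subject), str(r.group), str(r.fluid), int(r.replicate))
        for r in sample_meta.itertuples(index=False)
    ]
    metabolites = list(dict.fromkeys(df["metabolite"]))

    sample_index = {
        (s.subject_id, s.fluid, s.replicate): i for i, s in enumerate(samples)
    }
    met_index = {m: j for j, m in enumerate(metabolites)}
    matrix = np.full((len(samples), len(metabolites)), np.nan)
    for r in df.itertuples(index=False):
        i = sample_index[(str(r.subject), str(r.fluid), int(r.replicate))]
        matrix[i, met_index[r.metabolite]] = r.peak_area

    n_missing = int(np.isnan(matrix).sum())
    log.info(
        "read %d rows from %s -> %d samples x %d metabolites (%d missing cells)",
        len(df), path, len(samples), len(metabolites), n_missing,
    )
    return MetabolomicsDataset(samples, metabolites, matrix)


def write_peak_table(ds: MetabolomicsDataset, path, sep: str = ",") -> None:
    """Write a dataset in long format; numeric cells round-trip exactly.

    Missing cells are written as "NA" and read back as missing.
    """
    long = ds.to_long()
    long["peak_area"] = [
        "NA" if not np.isfinite(v) else repr(float(v)) for v in long["peak_area"]
    ]
    long.to_csv(path, sep=sep, index=False)


def average_replicates(ds: MetabolomicsDataset) -> MetabolomicsDataset:
    """Collapse replicates to one profile per (subject, fluid) by arithmetic mean.

    A cell of the averaged profile is missing only if it is missing in every
    replicate; otherwise it is the mean of the present replicate values.
    """
    order: list[tuple[str, str, str]] = []
    members: dict[tuple[str, str, str], list[int]] = {}
    for i, s in enumerate(ds.samples):
        key = (s.subject_id, s.group, s.fluid)
        if key not in members:
            members[key] = []
            order.append(key)
        members[key].append(i)

    out_samples = [SampleKey(sub, grp, fl, 1) for sub, grp, fl in order]
    matrix = np.empty((len(order), ds.n_metabolites))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices yield NaN
        for i, key in enumerate(order):
            matrix[i] = np.nanmean(ds.peak_area[members[key]], axis=0)
    return MetabolomicsDataset(out_samples, list(ds.metabolites), matrix)


def ln_transform(ds: MetabolomicsDataset, pseudocount: float = 0.0) -> MetabolomicsDataset:
    """Natural-log transform: cell = ln(peak_area + pseudocount).

    Cells where peak_area + pseudocount <= 0 become missing.
    """
    if pseudocount < 0:
        raise ParameterError(f"pseudocount must be non-negative, got {pseudocount}")
    shifted = ds.peak_area + pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(shifted > 0, np.log(shifted), np.nan)
    result = MetabolomicsDataset.__new__(MetabolomicsDataset)
    # bypass the non-negativity check: log values may legitimately be negative
    result.samples = list(ds.samples)
    result.metabolites = list(ds.metabolites)
    result.peak_area = out
    return result


def filter_detected(
    ds: MetabolomicsDataset, min_fraction_per_fluid: float = 0.8
) -> MetabolomicsDataset:
    """Keep metabolites detected in at least ``min_fraction_per_fluid`` of the
    samples of *each* fluid.  Order is preserved; the filter is idempotent."""
    if not 0.0 <= min_fraction_per_fluid <= 1.0:
        raise ParameterError("min_fraction_per_fluid must lie in [0, 1]")
    present = np.isfinite(ds.peak_area)
    keep = np.ones(ds.n_metabolites, dtype=bool)
    for fluid in FLUIDS:
        rows = [i for i, s in enumerate(ds.samples) if s.fluid == fluid]
        if not rows:
            continue
        frac = present[rows].mean(axis=0)
        keep &= frac >= min_fraction_per_fluid
    idx = np.flatnonzero(keep)
    kept = [ds.metabolites[j] for j in idx]
    log.info("detection filter: %d of %d metabolites retained", len(kept), ds.n_metabolites)
    result = MetabolomicsDataset.__new__(MetabolomicsDataset)
    result.samples = list(ds.samples)
    result.metabolites = kept
    result.peak_area = ds.peak_area[:, idx]
    return result


@dataclass
class PairedProfileTable:
    """Per-subject matched ln plasma / ln CSF profiles (replicates collapsed).

    ``s_pl`` and ``s_csf`` are [subjects x metabolites]; the pair mask is
    True only where both fluids are present.
    """

    subjects: list[tuple[str, str]]  # (subject_id, group)
    metabolites: list[str]
    s_pl: np.ndarray
    s_csf: np.ndarray

    def __post_init__(self) -> None:
        self.s_pl = np.asarray(self.s_pl, dtype=float)
        self.s_csf = np.asarray(self.s_csf, dtype=float)
        shape = (len(self.subjects), len(self.metabolites))
        if self.s_pl.shape != shape or self.s_csf.shape != shape:
            raise IntegrityError("paired matrices do not match subject/metabolite indices")

    @property
    def mask(self) -> np.ndarray:
        return np.isfinite(self.s_pl) & np.isfinite(self.s_csf)

    @property
    def groups(self) -> np.ndarray:
        return np.array([g for _, g in self.subjects])

    def scope_rows(self, scope: str) -> np.ndarray:
        """Row indices for a scope: 'combined', 'patients' or 'controls'."""
        if scope == "combined":
            return np.arange(len(self.subjects))
        if scope == "patients":
            return np.flatnonzero(self.groups == "glioma")
        if scope == "controls":
            return np.flatnonzero(self.groups == "control")
        raise ParameterError(f"unknown scope {scope!r}")


def build_paired_table(ds: MetabolomicsDataset) -> PairedProfileTable:
    """Assemble subject-matched plasma/CSF rows from an averaged, ln-transformed
    dataset.  Subjects lacking either fluid are dropped with a warning."""
    row_of: dict[tuple[str, str], int] = {}
    for i, s in enumerate(ds.samples):
        if (s.subject_id, s.fluid) in row_of:
            raise IntegrityError(
                f"multiple rows for ({s.subject_id}, {s.fluid}); average replicates first"
            )
        row_of[(s.subject_id, s.fluid)] = i

    subjects: list[tuple[str, str]] = []
    pl_rows: list[int] = []
    csf_rows: list[int] = []
    for sub in ds.subjects:
        if (sub, "plasma") in row_of and (sub, "csf") in row_of:
            subjects.append((sub, ds.group_of(sub)))
            pl_rows.append(row_of[(sub, "plasma")])
            csf_rows.append(row_of[(sub, "csf")])
        else:
            log.warning("subject %s lacks one fluid; dropped from paired table", sub)
    if not subjects:
        raise EmptyResultError("no subject has both plasma and CSF profiles")
    return PairedProfileTable(
        subjects, list(ds.metabolites), ds.peak_area[pl_rows], ds.peak_area[csf_rows]
    )


def pooled_matrix(ds: MetabolomicsDataset) -> tuple[pd.DataFrame, np.ndarray]:
    """Pooled view for the correlation network: one row per (subject, fluid)
    profile, both groups together.  Returns (row metadata, ln value matrix)."""
    meta = ds.sample_table()
    return meta, ds.peak_area.copy()
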
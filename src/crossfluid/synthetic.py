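"""Cohort simulator with planted correlation structure.

Generates replicate-level, two-fluid, two-group peak-area datasets in which
the per-metabolite plasma-CSF correlation, metabolite-metabolite block
structure, outlier contamination and replicate noise are all known, so every
downstream stage can be tested against ground truth.

Generative model (per subject s, metabolite m):

- latent (z_pl, z_csf) ~ bivariate normal, correlation rho[m, group(s)];
- metabolites sharing a block label mix in a subject-level factor common to
  both fluids, inducing pairwise cross-metabolite correlation;
- ln plasma value = mu_pl[m] + sd_pl[m] * x, similarly for CSF;
- optional outliers: the CSF latent of a random subject x metabolite subset
  is shifted by outlier_scale standard deviations (random sign);
- replicate peak areas = exp(latent) * lognormal noise with coefficient of
  variation replicate_cv on the area scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from crossfluid.core_io import MetabolomicsDataset, SampleKey
from crossfluid.errors import ParameterError


@dataclass
class SimulationConfig:
    n_glioma: int = 20
    n_control: int = 11
    n_replicates: int = 3
    n_metabolites: int = 101
    #: (M, 2) array of target correlations: column 0 patients, column 1 controls.
    rho_by_group: np.ndarray | None = None
    outlier_fraction: float = 0.0
    outlier_scale: float = 5.0
    replicate_cv: float = 0.1
    #: per-metabolite block label; 0 = no block, >0 = shared-factor block.
    block_assignment: np.ndarray | None = None
    block_loading: float = 0.95
    #: total screened metabolites; extras beyond n_metabolites are planted as
    #: poorly detected (missing in many CSF samples) to exercise the filter.
    n_screened: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_glioma < 2 or self.n_control < 2:
            raise ParameterError("cohort sizes must be >= 2")
        if self.n_replicates < 1:
            raise ParameterError("need >= 1 replicate")
        if not 0.0 <= self.outlier_fraction < 0.5:
            raise ParameterError("outlier_fraction must lie in [0, 0.5)")
        if self.outlier_fraction > 0 and self.outlier_scale <= 1.0:
            raise ParameterError("outlier_scale must exceed 1")
        if self.replicate_cv <= 0:
            raise ParameterError("replicate_cv must be positive")
        if not 0.0 <= self.block_loading < 1.0:
            raise ParameterError("block_loading must lie in [0, 1)")
        if self.rho_by_group is not None:
            self.rho_by_group = np.asarray(self.rho_by_group, dtype=float)
            if self.rho_by_group.shape != (self.n_metabolites, 2):
                raise ParameterError("rho_by_group must have shape (n_metabolites, 2)")
            if np.any(np.abs(self.rho_by_group) > 1):
                raise ParameterError("|rho| must be <= 1")
        if self.block_assignment is not None:
            self.block_assignment = np.asarray(self.block_assignment, dtype=int)
            if self.block_assignment.shape != (self.n_metabolites,):
                raise ParameterError("block_assignment must have shape (n_metabolites,)")
        if self.n_screened is not None and self.n_screened < self.n_metabolites:
            raise ParameterError("n_screened must be >= n_metabolites")


@dataclass
class SyntheticTruth:
    """Ground truth planted by :func:`simulate_dataset`."""

    metabolites: list[str]
    rho: np.ndarray                  # (M, 2) planted latent correlations
    rho_effective: np.ndarray        # (M, 2) after block-factor mixing
    blocks: np.ndarray               # (M,) block labels, 0 = none
    detected: list[str]              # metabolites planted as well detected
    lost_in_patients: list[str] = field(default_factory=list)
    lost_in_controls: list[str] = field(default_factory=list)
    shared_significant: list[str] = field(default_factory=list)


def _metabolite_ids(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"M{i + 1:0{width}d}" for i in range(n)]


def default_study_rho(n_metabolites: int = 101, seed: int = 0) -> np.ndarray:
    """A study-like mix of planted correlations.

    7 metabolites correlated in controls only, 10 in patients only, 16 in
    both groups, and the remainder split between moderate and near-null
    correlation in both groups.
    """
    if n_metabolites < 33:
        raise ParameterError("study-like mix needs >= 33 metabolites")
    rho = np.zeros((n_metabolites, 2))
    rho[:7] = (0.0, 0.9)        # lost in patients
    rho[7:17] = (0.9, 0.0)      # lost in controls
    rho[17:33] = (0.85, 0.85)   # shared
    rest = n_metabolites - 33
    half = rest // 2
    rho[33 : 33 + half] = (0.5, 0.5)
    rho[33 + half :] = (0.15, 0.15)
    return rho


def _classify_planted(
    ids: list[str], rho: np.ndarray, strong: float = 0.7, weak: float = 0.3
) -> tuple[list[str], list[str], list[str]]:
    lost_pat, lost_ctrl, shared = [], [], []
    for i, m in enumerate(ids):
        r_pat, r_ctrl = abs(rho[i, 0]), abs(rho[i, 1])
        if r_ctrl >= strong and r_pat <= weak:
            lost_pat.append(m)
        elif r_pat >= strong and r_ctrl <= weak:
            lost_ctrl.append(m)
        elif r_pat >= strong and r_ctrl >= strong:
            shared.append(m)
    return lost_pat, lost_ctrl, shared


def simulate_dataset(cfg: SimulationConfig) -> tuple[MetabolomicsDataset, SyntheticTruth]:
    """Draw a replicate-level dataset and its ground truth; reproducible from seed."""
    rng = np.random.default_rng(cfg.seed)
    m_main = cfg.n_metabolites
    m_total = cfg.n_screened if cfg.n_screened is not None else m_main
    ids = _metabolite_ids(m_total)

    rho = cfg.rho_by_group
    if rho is None:
        rho = default_study_rho(m_main) if m_main >= 33 else np.full((m_main, 2), 0.6)
    blocks = (
        cfg.block_assignment
        if cfg.block_assignment is not None
        else np.zeros(m_main, dtype=int)
    )

    subjects = [(f"G{i + 1:03d}", "glioma") for i in range(cfg.n_glioma)] + [
        (f"C{i + 1:03d}", "control") for i in range(cfg.n_control)
    ]
    n_sub = len(subjects)
    group_col = np.array([0 if g == "glioma" else 1 for _, g in subjects])

    mu_pl = rng.uniform(10.0, 16.0, size=m_total)
    mu_csf = mu_pl - rng.uniform(0.5, 2.5, size=m_total)
    sd_pl = rng.uniform(0.3, 1.0, size=m_total)
    sd_csf = rng.uniform(0.3, 1.0, size=m_total)

    # one shared factor per (subject, block)
    block_labels = sorted(set(blocks[blocks > 0]))
    factors = {b: rng.standard_normal(n_sub) for b in block_labels}

    lam = cfg.block_loading
    latent_pl = np.empty((n_sub, m_total))
    latent_csf = np.empty((n_sub, m_total))
    rho_eff = np.array(rho, dtype=float, copy=True)
    for j in range(m_total):
        if j < m_main:
            r = rho[j, group_col]  # per-subject target correlation
        else:
            r = np.zeros(n_sub)
        z1 = rng.standard_normal(n_sub)
        z2 = rng.standard_normal(n_sub)
        x = z1
        y = r * z1 + np.sqrt(1.0 - r**2) * z2
        if j < m_main and blocks[j] > 0 and lam > 0:
            f = factors[blocks[j]]
            x = np.sqrt(1.0 - lam**2) * x + lam * f
            y = np.sqrt(1.0 - lam**2) * y + lam * f
            rho_eff[j] = (1.0 - lam**2) * rho[j] + lam**2
        latent_pl[:, j] = mu_pl[j] + sd_pl[j] * x
        latent_csf[:, j] = mu_csf[j] + sd_csf[j] * y

    if cfg.outlier_fraction > 0:
        hit = rng.random((n_sub, m_main)) < cfg.outlier_fraction
        signs = rng.choice([-1.0, 1.0], size=(n_sub, m_main))
        latent_csf[:, :m_main] += hit * signs * cfg.outlier_scale * sd_csf[:m_main]

    # poorly detected extras: missing in >= 40% of CSF profiles
    undetected_csf: dict[int, np.ndarray] = {}
    for j in range(m_main, m_total):
        k = max(1, int(np.ceil(0.4 * n_sub)) + int(rng.integers(0, n_sub // 3 + 1)))
        undetected_csf[j] = rng.choice(n_sub, size=min(k, n_sub), replace=False)

    sigma_ln = np.sqrt(np.log1p(cfg.replicate_cv**2))
    samples: list[SampleKey] = []
    rows: list[np.ndarray] = []
    for i, (sub, grp) in enumerate(subjects):
        for fluid, latent in (("plasma", latent_pl), ("csf", latent_csf)):
            base = np.exp(latent[i])
            for rep in range(1, cfg.n_replicates + 1):
                noise = np.exp(sigma_ln * rng.standard_normal(m_total) - 0.5 * sigma_ln**2)
                area = base * noise
                if fluid == "csf":
                    for j, bad in undetected_csf.items():
                        if i in bad:
                            area[j] = np.nan
                samples.append(SampleKey(sub, grp, fluid, rep))
                rows.append(area)

    ds = MetabolomicsDataset(samples, ids, np.vstack(rows))
    lost_pat, lost_ctrl, shared = _classify_planted(ids[:m_main], rho)
    truth = SyntheticTruth(
        metabolites=ids[:m_main],
        rho=np.array(rho),
        rho_effective=rho_eff,
        blocks=np.array(blocks),
        detected=ids[:m_main],
        lost_in_patients=lost_pat,
        lost_in_controls=lost_ctrl,
        shared_significant=shared,
    )
    return ds, truth


def write_fixture_gmt(
    path,
    n_pathways: int,
    truth: SyntheticTruth,
    seed: int = 0,
    max_size: int = 165,
) -> list[str]:
    """Write a fixture GMT pathway collection over the simulated metabolites.

    For every planted block one set is written whose membership is at least
    half drawn from that block (name ``BLOCK<b>_SET``); the remaining sets are
    random draws from the universe.  Set sizes span 5..max_size, clipped to
    the universe size.  Returns the list of set names written.
    """
    rng = np.random.default_rng(seed)
    universe = list(truth.metabolites)
    names: list[str] = []
    lines: list[str] = []

    block_labels = sorted({int(b) for b in truth.blocks if b > 0})
    for b in block_labels:
        members_in = [m for m, bl in zip(truth.metabolites, truth.blocks) if bl == b]
        n_in = max(3, int(np.ceil(len(members_in) * 0.8)))
        chosen = list(rng.choice(members_in, size=min(n_in, len(members_in)), replace=False))
        n_out = max(0, min(len(chosen) - 1, len(universe) - len(chosen)))
        others = [m for m in universe if m not in chosen]
        if n_out and others:
            chosen += list(rng.choice(others, size=min(n_out, len(others)), replace=False))
        name = f"BLOCK{b}_SET"
        names.append(name)
        lines.append("\t".join([name, f"planted block {b} pathway", *chosen]))

    for k in range(n_pathways - len(block_labels)):
        size = int(rng.integers(5, min(max_size, len(universe)) + 1))
        members = list(rng.choice(universe, size=size, replace=False))
        name = f"RANDOM_SET_{k + 1}"
        names.append(name)
        lines.append("\t".join([name, "random pathway", *members]))

    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
    return names
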
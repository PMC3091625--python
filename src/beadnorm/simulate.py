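"""Synthetic bead-array experiments with known truth.

The generator emulates a small time-course expression experiment on an
Illumina-style bead chip: three groups (time points) of four replicate
arrays, bead-summarised probe intensities with bead standard errors and bead
counts, a panel of negative-control beads, a small set of truly deregulated
probes, and a matched reference fold-change table standing in for qRT-PCR
validation measurements.

Observation model for probe g on array j (group i):

    y_gij = b_gij + s_gi * a_j * exp(eta_gij)

with additive background ``b ~ Normal(bg_mean, bg_sd^2)`` truncated at zero,
true expression ``s_gi = 2**(baseline_g + delta_gi)`` (``delta = 0`` for
non-deregulated probes), array scale factor ``a_j`` (log-normal), and
multiplicative noise ``eta ~ Normal(0, mult_cv^2)``.  Negative-control beads
carry background only.  This produces the additive-plus-multiplicative
variance-mean structure that variance-stabilizing transforms assume: on the
raw scale the replicate SD is roughly constant (~bg_sd) for unexpressed
probes and grows linearly with the mean for expressed ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import (
    ControlProfile,
    ProbeProfileTable,
    ReferenceFoldChanges,
    SampleDesign,
)

__all__ = [
    "SimulationConfig",
    "TruthSet",
    "simulate_experiment",
    "simulate_reference_fold_changes",
]

# Deterministic sub-stream indices: one generator per noise component so that
# e.g. changing the bead-count model never perturbs the signal draws.
_STREAMS = {"background": 0, "signal": 1, "beads": 2, "scale": 3, "effects": 4,
            "reference": 5}


def _rng(seed: int, component: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[component]])


@dataclass
class SimulationConfig:
    """Study conditions of a simulated bead-array experiment.

    Defaults emulate the design this package's measures were built around:
    three time-point groups with four replicate arrays each, ~15 beads per
    probe on average, and a 20-gene true-positive panel with reference fold
    changes.
    """

    n_probes: int = 5000
    n_negative_controls: int = 500
    #: ordered mapping group label -> number of replicate arrays
    groups: dict[str, int] = field(
        default_factory=lambda: {"2h": 4, "4h": 4, "12h": 4}
    )
    de_fraction: float = 0.05
    #: |log2 fold change| of deregulated probes drawn uniformly in this range
    effect_low: float = 1.0
    effect_high: float = 2.0
    baseline_log2_mean: float = 7.0
    baseline_log2_sd: float = 2.0
    bg_mean: float = 100.0
    bg_sd: float = 25.0
    mult_cv: float = 0.2
    #: SD of log array scale factors (log-normal); 0 disables scale distortion
    array_scale_sd: float = 0.1
    mean_beads: float = 15.0
    n_tp_genes: int = 20
    reference_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_probes <= 0 or self.n_negative_controls <= 0:
            raise ValueError("probe and control counts must be positive")
        if not self.groups or any(n <= 0 for n in self.groups.values()):
            raise ValueError("every group needs at least one replicate")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")
        if self.mult_cv < 0 or self.bg_sd < 0 or self.reference_noise_sd < 0:
            raise ValueError("noise parameters must be non-negative")
        if self.mean_beads < 1:
            raise ValueError("mean_beads must be >= 1")

    @property
    def n_samples(self) -> int:
        return sum(self.groups.values())

    @property
    def sample_ids(self) -> list[str]:
        return [f"{g}_r{r + 1}" for g, n in self.groups.items() for r in range(n)]

    @property
    def comparisons(self) -> list[tuple[str, str]]:
        """All ordered (test, reference) group pairs, later vs earlier."""
        labels = list(self.groups)
        return [(labels[j], labels[i])
                for i in range(len(labels)) for j in range(i + 1, len(labels))]


@dataclass
class TruthSet:
    """Ground truth of a simulated experiment."""

    de_flags: pd.Series                  # bool per probe
    true_log2fc: pd.DataFrame            # probe x comparison ("<t>_vs_<r>")
    tp_genes: list[str]                  # designated true-positive panel
    reference_fc: ReferenceFoldChanges   # noisy qRT-PCR-like measurements
    baseline_log2: pd.Series             # true log2 expression per probe

    def __post_init__(self) -> None:
        de = set(self.de_flags.index[self.de_flags])
        if not set(self.tp_genes) <= de:
            raise ValueError("tp_genes must be a subset of deregulated probes")
        non_de = self.true_log2fc.loc[~self.de_flags]
        if len(non_de) and not (non_de.values == 0).all():
            raise ValueError("non-deregulated probes must have zero true log2fc")


def _truncated_normal(rng, mean, sd, size):
    """Normal(mean, sd) truncated at zero, drawn via scipy's truncnorm."""
    if sd == 0:
        return np.full(size, mean, dtype=float)
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd,
                               size=size, random_state=rng)


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[ProbeProfileTable, ControlProfile, SampleDesign, TruthSet]:
    """Generate one complete experiment under ``config``.

    Returns the probe profile (with bead SE, bead counts and detection
    p-values), the negative-control profile, the sample design and the
    :class:`TruthSet`.  Identical config (including seed) yields identical
    output.
    """
    cfg = config
    probes = [f"probe_{i:05d}" for i in range(cfg.n_probes)]
    controls = [f"negctrl_{i:04d}" for i in range(cfg.n_negative_controls)]
    samples = cfg.sample_ids
    group_of = np.concatenate(
        [[g] * n for g, n in cfg.groups.items()]
    )
    n_s = cfg.n_samples

    eff_rng = _rng(cfg.seed, "effects")
    baseline = eff_rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd,
                              cfg.n_probes)
    n_de = int(round(cfg.de_fraction * cfg.n_probes))
    de_idx = eff_rng.choice(cfg.n_probes, size=n_de, replace=False)
    de_flags = np.zeros(cfg.n_probes, dtype=bool)
    de_flags[de_idx] = True

    # per-probe group effects delta_gi; first group is the reference (0)
    labels = list(cfg.groups)
    delta = np.zeros((cfg.n_probes, len(labels)))
    if n_de:
        mags = eff_rng.uniform(cfg.effect_low, cfg.effect_high,
                               size=(n_de, len(labels) - 1))
        signs = eff_rng.choice([-1.0, 1.0], size=(n_de, len(labels) - 1))
        delta[de_idx, 1:] = mags * signs

    comparisons = cfg.comparisons
    comp_names = [f"{t}_vs_{r}" for t, r in comparisons]
    fc = np.zeros((cfg.n_probes, len(comparisons)))
    for c, (t, r) in enumerate(comparisons):
        fc[:, c] = delta[:, labels.index(t)] - delta[:, labels.index(r)]

    # true-positive panel: deregulated probes stratified across baseline
    # expression terciles so the panel covers a broad intensity range
    tp_genes: list[str] = []
    if n_de and cfg.n_tp_genes:
        n_tp = min(cfg.n_tp_genes, n_de)
        de_sorted = de_idx[np.argsort(baseline[de_idx])]
        terciles = np.array_split(de_sorted, 3)
        want = [n_tp // 3 + (1 if k < n_tp % 3 else 0) for k in range(3)]
        chosen: list[int] = []
        for k, (chunk, w) in enumerate(zip(terciles, want)):
            take = min(w, len(chunk))
            if take:
                chosen.extend(eff_rng.choice(chunk, size=take, replace=False))
        # top up from anywhere if a tercile was short
        remaining = [i for i in de_sorted if i not in set(chosen)]
        while len(chosen) < n_tp and remaining:
            chosen.append(remaining.pop(0))
        tp_genes = [probes[i] for i in sorted(chosen)]

    # --- signal construction -------------------------------------------------
    scale_rng = _rng(cfg.seed, "scale")
    if cfg.array_scale_sd > 0:
        a_j = np.exp(scale_rng.normal(0.0, cfg.array_scale_sd, n_s))
    else:
        a_j = np.ones(n_s)

    sig_rng = _rng(cfg.seed, "signal")
    group_col = np.array([labels.index(g) for g in group_of])
    s_gi = 2.0 ** (baseline[:, None] + delta[:, group_col])  # probe x sample
    eta = (sig_rng.normal(0.0, cfg.mult_cv, size=(cfg.n_probes, n_s))
           if cfg.mult_cv > 0 else np.zeros((cfg.n_probes, n_s)))
    expressed = s_gi * a_j[None, :] * np.exp(eta)

    bg_rng = _rng(cfg.seed, "background")
    b_probe = _truncated_normal(bg_rng, cfg.bg_mean, cfg.bg_sd,
                                (cfg.n_probes, n_s))
    b_ctrl = _truncated_normal(bg_rng, cfg.bg_mean, cfg.bg_sd,
                               (cfg.n_negative_controls, n_s))
    y = b_probe + expressed

    # --- bead-level summaries ------------------------------------------------
    bead_rng = _rng(cfg.seed, "beads")
    n_beads = 1 + bead_rng.poisson(max(cfg.mean_beads - 1.0, 0.0),
                                   size=(cfg.n_probes, n_s))
    bead_sd = np.sqrt(cfg.bg_sd ** 2 + (cfg.mult_cv * expressed) ** 2)
    bead_se = bead_sd / np.sqrt(n_beads)

    # detection p: 1 - rank fraction of the signal among that sample's
    # negative controls (operational stand-in for bead-level detection)
    detection = np.empty_like(y)
    for j in range(n_s):
        below = np.searchsorted(np.sort(b_ctrl[:, j]), y[:, j], side="left")
        detection[:, j] = 1.0 - below / cfg.n_negative_controls

    profile = ProbeProfileTable(
        avg_signal=pd.DataFrame(y, index=probes, columns=samples),
        bead_stderr=pd.DataFrame(bead_se, index=probes, columns=samples),
        n_beads=pd.DataFrame(n_beads, index=probes, columns=samples),
        detection_p=pd.DataFrame(detection, index=probes, columns=samples),
    )
    ctrl = ControlProfile(pd.DataFrame(b_ctrl, index=controls, columns=samples))
    design = SampleDesign(pd.DataFrame({
        "sample_id": samples,
        "group": group_of,
        "replicate": [r + 1 for _, n in cfg.groups.items() for r in range(n)],
    }))
    truth = TruthSet(
        de_flags=pd.Series(de_flags, index=probes),
        true_log2fc=pd.DataFrame(fc, index=probes, columns=comp_names),
        tp_genes=tp_genes,
        reference_fc=ReferenceFoldChanges(
            pd.DataFrame(columns=["gene_id", "comparison", "log2_ratio"])
            if not tp_genes else _reference_table(
                tp_genes, comp_names,
                pd.DataFrame(fc, index=probes, columns=comp_names),
                cfg.reference_noise_sd, _rng(cfg.seed, "reference"))
        ),
        baseline_log2=pd.Series(baseline, index=probes),
    )
    return profile, ctrl, design, truth


def _reference_table(genes, comp_names, true_fc, noise_sd, rng) -> pd.DataFrame:
    rows = []
    for g in genes:
        for c in comp_names:
            noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            rows.append((g, c, float(true_fc.at[g, c]) + noise))
    return pd.DataFrame(rows, columns=["gene_id", "comparison", "log2_ratio"])


def simulate_reference_fold_changes(
    truth: TruthSet, noise_sd: float, seed: int
) -> ReferenceFoldChanges:
    """Re-draw the qRT-PCR-like reference table with fresh measurement noise.

    Each true-positive gene's true log2 fold change receives independent
    ``Normal(0, noise_sd^2)`` measurement error per comparison.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if not truth.tp_genes:
        raise ValueError("truth set has no true-positive panel")
    rng = _rng(seed, "reference")
    return ReferenceFoldChanges(_reference_table(
        truth.tp_genes, list(truth.true_log2fc.columns),
        truth.true_log2fc, noise_sd, rng))
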
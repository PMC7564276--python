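"""Simulation experiments that validate the whole chain end to end.

These are the package's calibration studies: the empirical familywise
type-I error of the cluster permutation test on null synthetic data,
the power to recover a planted parahippocampal↔posterior-cingulate
alpha-band effect, and the monotonicity of detected cluster mass in
planted coupling strength. Used by the test suite, the analysis
drivers and the acceptance script.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .pipeline import PipelineConfig, run_study
from .synthetic import StudySpec, default_effect_couplings, generate_crossover_study

__all__ = [
    "null_alpha_pli_config",
    "null_type_i_error",
    "planted_effect_runs",
    "strength_sweep",
    "PLANTED_EDGES",
]

#: The four planted alpha-band edges (order-normalized label pairs).
PLANTED_EDGES: tuple[tuple[str, str], ...] = (
    ("L ParaH", "L PCC"),
    ("L ParaH", "R PCC"),
    ("L PCC", "R ParaH"),
    ("R ParaH", "R PCC"),
)


def null_alpha_pli_config(n_permutations: int = 500, seed: int = 0) -> PipelineConfig:
    """Alpha-band PLI-only configuration used by the simulation studies.

    Restricting to the contrast of interest keeps a 200-dataset
    calibration run at desk scale without changing any estimator
    setting (epochs, threshold, permutation scheme are the defaults).
    """
    cfg = PipelineConfig(n_permutations=n_permutations, seed=seed)
    return replace(cfg, metrics=("pli",), bands=(cfg.bands[0],))


def _null_spec(seed: int, n_subjects: int = 8, fs: float = 256.0) -> StudySpec:
    return StudySpec(n_subjects=n_subjects, fs=fs, duration=60.0, seed=seed)


def null_type_i_error(
    n_datasets: int = 200,
    n_subjects: int = 8,
    n_permutations: int = 500,
    alphas: tuple[float, ...] = (0.05,),
    base_seed: int = 1,
    fs: float = 256.0,
) -> dict:
    """Familywise type-I error of the cluster test on null data.

    Generates ``n_datasets`` crossover datasets with no planted
    couplings (dataset seeds ``base_seed + i``), runs the alpha-band
    PLI pipeline on each dataset's SM pre/post contrast, and records
    the smallest cluster p-value per dataset. The reported rate at
    level a is the fraction of datasets whose smallest p is below a —
    i.e. the probability of declaring *any* cluster significant when
    nothing is there.

    Returns a dict with per-alpha rates, their binomial standard
    errors, and the vector of per-dataset minimum p-values.
    """
    min_ps = np.empty(n_datasets)
    for i in range(n_datasets):
        seed = base_seed + i
        spec = _null_spec(seed, n_subjects=n_subjects, fs=fs)
        dataset = generate_crossover_study(spec, sessions=("SM",))
        cfg = null_alpha_pli_config(n_permutations=n_permutations, seed=seed)
        result = run_study(dataset, cfg, sessions=("SM",))
        min_ps[i] = result.tests[("pli", "alpha", "SM")].min_p
    rates = {}
    for a in alphas:
        rate = float(np.mean(min_ps < a))
        se = float(np.sqrt(a * (1 - a) / n_datasets))
        rates[a] = {"rate": rate, "binomial_se": se}
    return {"rates": rates, "min_p": min_ps, "n_datasets": n_datasets}


@dataclass
class PlantedRun:
    seed: int
    sm_significant: bool
    sm_positive_cluster_edges: tuple[tuple[str, str], ...]
    n_planted_recovered: int
    ctrl_significant: bool
    sm_max_pos_mass: float


def planted_effect_runs(
    n_runs: int = 5,
    n_subjects: int = 24,
    strength: float = 0.35,
    n_permutations: int = 500,
    base_seed: int = 1,
    fs: float = 256.0,
    sessions: tuple[str, ...] = ("Ctrl", "SM"),
) -> list[PlantedRun]:
    """Recovery of the planted 4-edge alpha effect at full study size.

    Each run generates a crossover study whose SM-post recordings carry
    the parahippocampal↔posterior-cingulate alpha couplings, runs the
    alpha-band PLI pipeline on both sessions, and reports whether the
    SM contrast shows a significant positive cluster, how many of the
    four planted edges that cluster covers, and whether the Ctrl
    contrast (which should stay null) shows anything.
    """
    runs = []
    for i in range(n_runs):
        seed = base_seed + i
        spec = StudySpec(
            n_subjects=n_subjects, fs=fs, duration=60.0, seed=seed,
            effect_couplings=default_effect_couplings(strength=strength),
        )
        dataset = generate_crossover_study(spec, sessions=sessions)
        cfg = null_alpha_pli_config(n_permutations=n_permutations, seed=seed)
        result = run_study(dataset, cfg, sessions=sessions)
        sm = result.tests[("pli", "alpha", "SM")]
        sig_pos = [c for c in sm.clusters_pos if c.p_value is not None and c.p_value < cfg.alpha]
        edges: tuple[tuple[str, str], ...] = ()
        recovered = 0
        if sig_pos:
            top = max(sig_pos, key=lambda c: c.mass)
            edges = top.edges
            norm = {tuple(sorted(e)) for e in edges}
            recovered = sum(1 for e in PLANTED_EDGES if tuple(sorted(e)) in norm)
        ctrl_sig = False
        if "Ctrl" in sessions:
            ctrl_sig = bool(result.tests[("pli", "alpha", "Ctrl")].significant())
        runs.append(
            PlantedRun(
                seed=seed,
                sm_significant=bool(sig_pos),
                sm_positive_cluster_edges=edges,
                n_planted_recovered=recovered,
                ctrl_significant=ctrl_sig,
                sm_max_pos_mass=max((c.mass for c in sm.clusters_pos), default=0.0),
            )
        )
    return runs


def strength_sweep(
    strengths: tuple[float, ...] = (0.1, 0.25, 0.5),
    n_runs: int = 3,
    n_subjects: int = 10,
    n_permutations: int = 200,
    base_seed: int = 11,
) -> dict[float, float]:
    """Median detected positive cluster mass vs planted coupling strength.

    Detection strength should not decrease as the planted coupling
    grows; used to check monotonicity of the whole chain.
    """
    out: dict[float, float] = {}
    for s in strengths:
        masses = []
        for i in range(n_runs):
            runs = planted_effect_runs(
                n_runs=1, n_subjects=n_subjects, strength=s,
                n_permutations=n_permutations, base_seed=base_seed + i,
                sessions=("SM",),
            )
            masses.append(runs[0].sm_max_pos_mass)
        out[s] = float(np.median(masses))
    return out
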
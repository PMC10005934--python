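"""Monte-Carlo calibration suites for the statistics engine and pipeline.

These routines measure, by simulation, the operating characteristics the
analysis relies on: type-I error of the covariate-adjusted ANCOVA, the
false-discovery proportion of BH-corrected regional testing, coverage of the
percentile bootstrap CI on partial eta-squared, and end-to-end power /
regional recovery for effects planted at the connectivity level.  They are
used by the validation tests and the reproduction script; none is part of
the headline analysis path.
"""

from __future__ import annotations

import numpy as np

from .connectome import binarize
from .controllability import controllability_table, node_controllability
from .simulate import GeneratorConfig, generate_cohort, simulate_outcome_table
from .stats import AncovaSpec, bh_fdr, bootstrap_ci_eta, build_design, fit_ancova

__all__ = [
    "type_i_error_rate",
    "bh_false_discovery_proportion",
    "bootstrap_coverage",
    "pipeline_group_effect",
    "group_effect_power",
    "regional_recovery",
]

_DIAG_SPEC = AncovaSpec(
    dependent="wb_modal",
    effect="diagnosis",
    covariates=("age", "gender", "site", "edge_count"),
    n_boot=0,
    name="diagnosis",
)


def type_i_error_rate(
    n_reps: int = 1000, n_per_group: int = 100, alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Rejection rate of the diagnosis ANCOVA under a simulated null.

    Outcomes are generated with zero diagnosis coefficient (covariate
    effects present), so every rejection is a false positive.
    """
    ss = np.random.SeedSequence([seed, 101])
    hits = 0
    for child in ss.spawn(n_reps):
        rng = np.random.default_rng(child)
        table = simulate_outcome_table(n_per_group, n_per_group, rng)
        r = fit_ancova(_DIAG_SPEC, table)
        hits += r.p < alpha
    return hits / n_reps


def bh_false_discovery_proportion(
    n_reps: int = 500, m: int = 114, q: float = 0.05, seed: int = 0
) -> float:
    """Mean false-discovery proportion of BH over independent null p-values.

    Under the complete null every discovery is false, so FDP is 1 whenever
    anything is rejected; BH guarantees the mean is <= q.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    fdp = 0.0
    for _ in range(n_reps):
        p = rng.uniform(size=m)
        _, flags = bh_fdr(p, q=q)
        fdp += float(flags.any())
    return fdp / n_reps


def bootstrap_coverage(
    n_reps: int = 500,
    n_per_group: int = 100,
    beta: float = 0.667,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Coverage of the 95% percentile bootstrap CI for partial eta-squared.

    The planted effect is a group mean shift of ``beta`` on unit-variance
    noise with balanced groups, so the population partial eta-squared is
    known in closed form:  eta^2 = beta^2 * 0.25 / (beta^2 * 0.25 + 1).
    Returns (coverage, true_eta_sq).
    """
    true_eta = beta**2 * 0.25 / (beta**2 * 0.25 + 1.0)
    ss = np.random.SeedSequence([seed, 303])
    covered = 0
    for child in ss.spawn(n_reps):
        rng = np.random.default_rng(child)
        table = simulate_outcome_table(
            n_per_group, n_per_group, rng, effect_sizes={"diagnosis": beta}
        )
        d = build_design(_DIAG_SPEC, table)
        lo, hi = bootstrap_ci_eta(d, n_boot=n_boot, rng=rng)
        covered += lo <= true_eta <= hi
    return covered / n_reps, true_eta


def pipeline_group_effect(
    delta: float,
    n_per_group: int = 200,
    n_nodes: int = 114,
    seed: int = 0,
    regional_effects: dict | None = None,
):
    """One full connectivity-level run: simulate -> controllability -> table.

    Returns the merged cohort table and node labels; ``delta`` scales
    patient hub-edge prevalence (0 = null cohort).
    """
    cfg = GeneratorConfig(
        n_nodes=n_nodes, n_hc=n_per_group, n_mdd=n_per_group, seed=seed,
        group_effect=delta, regional_effects=regional_effects or {},
    )
    cohort, table, truth = generate_cohort(cfg)
    profiles = [
        node_controllability(binarize(sc), sc.subject_id) for sc in cohort
    ]
    ctrl = controllability_table(profiles, cohort[0].node_labels)
    return table.join(ctrl), list(cohort[0].node_labels), truth


def group_effect_power(
    delta: float,
    n_reps: int = 20,
    n_per_group: int = 200,
    n_nodes: int = 114,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Detection rate of a planted hub-connectivity group effect.

    Each replicate runs the entire pipeline (sample connectomes, binarize,
    normalize, controllability, covariate-adjusted ANCOVA on whole-brain
    modal controllability).
    """
    base = np.random.SeedSequence([seed, 404]).generate_state(n_reps) % 2**31
    hits = 0
    for s in base:
        merged, _, _ = pipeline_group_effect(
            delta, n_per_group=n_per_group, n_nodes=n_nodes, seed=int(s)
        )
        r = fit_ancova(_DIAG_SPEC, merged)
        hits += r.p < alpha
    return hits / n_reps


def regional_recovery(
    regional_delta: float,
    planted_nodes: tuple[int, ...] = (5, 40, 90),
    n_per_group: int = 200,
    n_nodes: int = 114,
    seed: int = 0,
):
    """Regional FDR screen on a cohort with node-level planted effects.

    Returns (flagged node indices, planted node indices).  Planted effects
    scale every edge of the chosen nodes for the patient group, so their
    controllability shifts propagate physically to neighbouring regions;
    recovery is judged as flagged-set containment of the planted set.
    """
    from .stats import run_regional_analysis

    merged, labels, truth = pipeline_group_effect(
        0.0, n_per_group=n_per_group, n_nodes=n_nodes, seed=seed,
        regional_effects={int(i): regional_delta for i in planted_nodes},
    )
    spec = AncovaSpec(
        dependent="modal_ctrl", effect="diagnosis",
        covariates=("age", "gender", "site", "edge_count"), n_boot=0,
    )
    reg = run_regional_analysis(spec, merged, labels)
    flagged = {i for i, s in enumerate(reg.significant) if s}
    return flagged, set(int(i) for i in planted_nodes)
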
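"""Synthetic cohort and expression-matrix generators.

Trait cohorts are returned as pandas DataFrames with one row per individual
and the columns

    individual_id, trait, genotype, sex, litter_id, site_or_era, weight,
    age_group, true_class

``true_class`` is the generating component ("lean"/"heavy") and exists only
so recovery tests can score estimates; fitting code accepts trait arrays and
never sees it.  Survey weights are uniform (1.0) by default; an optional
two-stratum mode exercises weighted fitting.

Expression data are returned as an :class:`ExpressionExperiment` holding a
genes x samples matrix on both Ct and linear-abundance scales plus sample
annotations (adiposity label and latent marker class).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .scenarios import ExpressionScenario, SwitchScenario

__all__ = [
    "simulate_cohort",
    "simulate_two_era",
    "simulate_expression",
    "ExpressionExperiment",
]

COHORT_COLUMNS = [
    "individual_id", "trait", "genotype", "sex", "litter_id",
    "site_or_era", "weight", "age_group", "true_class",
]


def _resolve_seed(scenario, seed: Optional[int]) -> Optional[int]:
    return seed if seed is not None else scenario.seed


def simulate_cohort(
    scenario: SwitchScenario,
    seed: Optional[int] = None,
    n_wildtype: int = 0,
    weight_mode: str = "uniform",
) -> pd.DataFrame:
    """Draw a cohort from a two-component Gaussian switch scenario.

    Each mutant individual enters the heavy component with probability
    ``scenario.pi_on`` and is otherwise lean; wild-type individuals
    (``n_wildtype`` of them, genotype "WT") are drawn from the lean
    component only.  When ``scenario.litter_size`` is set, individuals are
    assigned to litters and, if ``litter_sd_frac > 0``, a shared per-litter
    normal effect is added to the trait.

    Parameters
    ----------
    scenario : SwitchScenario
    seed : int, optional
        Overrides ``scenario.seed``.  Identical scenario + seed gives a
        bitwise-identical cohort.
    n_wildtype : int
        Number of wild-type littermates to add (default 0).
    weight_mode : {"uniform", "two_stratum"}
        Survey-weight column: all 1.0, or two strata with weights 0.5 / 1.5
        (mean 1) to exercise weighted fitting.
    """
    rng = np.random.default_rng(_resolve_seed(scenario, seed))
    n_mut = scenario.n
    n_total = n_mut + n_wildtype

    heavy = np.zeros(n_total, dtype=bool)
    heavy[:n_mut] = rng.random(n_mut) < scenario.pi_on

    mu = np.where(heavy, scenario.mu_heavy, scenario.mu_lean)
    sigma = np.where(heavy, scenario.sigma_heavy, scenario.sigma_lean)
    trait = rng.normal(mu, sigma)

    if scenario.litter_size is not None:
        per_litter = max(1, int(round(scenario.litter_size)))
        n_litters = int(np.ceil(n_total / per_litter))
        litter_id = rng.permutation(np.arange(n_total) % n_litters)
        litter_id = np.array([f"L{i:03d}" for i in litter_id])
        if scenario.litter_sd_frac > 0:
            effects = rng.normal(
                0.0, scenario.litter_sd_frac * scenario.mu_lean, n_litters
            )
            idx = np.array([int(l[1:]) for l in litter_id])
            trait = trait + effects[idx]
    else:
        litter_id = np.array([""] * n_total)

    if weight_mode == "uniform":
        weight = np.ones(n_total)
    elif weight_mode == "two_stratum":
        stratum = rng.random(n_total) < 0.5
        weight = np.where(stratum, 0.5, 1.5)
    else:
        raise ValueError(f"unknown weight_mode {weight_mode!r}")

    genotype = np.array(["mutant"] * n_mut + ["WT"] * n_wildtype)
    sex = rng.choice(["M", "F"], size=n_total)

    return pd.DataFrame({
        "individual_id": [f"{scenario.name}_{i:05d}" for i in range(n_total)],
        "trait": trait,
        "genotype": genotype,
        "sex": sex,
        "litter_id": litter_id,
        "site_or_era": scenario.name,
        "weight": weight,
        "age_group": "all",
        "true_class": np.where(heavy, "heavy", "lean"),
    })[COHORT_COLUMNS]


def simulate_two_era(
    scenario_a: SwitchScenario,
    scenario_b: SwitchScenario,
    seed: Optional[int] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw two independent cohorts labelled by era.

    The two child seeds are spawned deterministically from ``seed`` (or
    from ``scenario_a.seed`` when ``seed`` is None), so the pair is
    reproducible from a single integer.
    """
    base = seed if seed is not None else (scenario_a.seed or 0)
    child_a, child_b = np.random.SeedSequence(base).spawn(2)
    seed_a = int(child_a.generate_state(1)[0] % (2**31))
    seed_b = int(child_b.generate_state(1)[0] % (2**31))
    cohort_a = simulate_cohort(scenario_a, seed=seed_a)
    cohort_b = simulate_cohort(scenario_b, seed=seed_b)
    return cohort_a, cohort_b


@dataclass
class ExpressionExperiment:
    """Genes x samples expression data on Ct and abundance scales.

    Attributes
    ----------
    ct : pandas.DataFrame
        Threshold-cycle matrix (genes in rows, samples in columns).
    abundance : pandas.DataFrame
        Linear-scale abundances (2**log2_expression), same shape.
    sample_annotations : pandas.DataFrame
        Indexed by sample; columns ``adiposity`` ("obese"/"lean"),
        ``marker_class`` ("low"/"high", the latent ground truth) and ``sex``.
    """

    ct: pd.DataFrame
    abundance: pd.DataFrame
    sample_annotations: pd.DataFrame


def simulate_expression(
    scenario: ExpressionScenario, seed: Optional[int] = None
) -> ExpressionExperiment:
    """Generate an expression cohort with two latent marker classes.

    The marker gene is expressed ``marker_effect`` log2 units lower in the
    marker-low class.  Panel genes are suppressed by ``panel_suppression``
    log2 units only in samples that are both marker-low and obese.
    Housekeeping genes carry no class or adiposity effect.  A
    ``background_class_frac`` slice of background genes receives
    marker-class-linked offsets so the marker class dominates
    between-sample variance, as in adipose transcriptomes stratifying by
    TRIM28 rather than by adiposity.
    """
    rng = np.random.default_rng(_resolve_seed(scenario, seed))
    n_s, n_g = scenario.n_samples, scenario.n_genes

    samples = [f"S{i:03d}" for i in range(n_s)]
    marker_low = rng.random(n_s) < scenario.frac_marker_low
    obese = rng.random(n_s) < scenario.frac_obese
    sex = rng.choice(["M", "F"], size=n_s)

    named = [scenario.marker_gene, *scenario.panel_genes, *scenario.housekeeping_genes]
    n_background = n_g - len(named)
    background = [f"GENE{i:05d}" for i in range(n_background)]
    genes = named + background

    base = rng.normal(6.0, 1.5, size=n_g)  # per-gene baseline log2 expression
    log2 = np.tile(base[:, None], (1, n_s))

    # marker: lower in the latent low class
    log2[0, marker_low] -= scenario.marker_effect
    # panel: suppressed only in marker-low AND obese samples
    hit = marker_low & obese
    panel_rows = slice(1, 1 + len(scenario.panel_genes))
    log2[panel_rows, :] = np.where(
        hit[None, :],
        log2[panel_rows, :] - scenario.panel_suppression,
        log2[panel_rows, :],
    )
    # housekeeping rows: no effect; background genes: marker-class structure
    n_named = len(named)
    n_struct = int(round(scenario.background_class_frac * n_background))
    if n_struct > 0:
        offsets = rng.normal(0.0, scenario.background_class_sd, size=n_struct)
        rows = np.arange(n_named, n_named + n_struct)
        log2[rows[:, None], np.where(marker_low)[0][None, :]] += offsets[:, None]
    # a weak adiposity signature on a small slice, so obesity is present but
    # subordinate in sample-space variance
    n_ob = max(1, n_background // 10)
    ob_rows = np.arange(n_g - n_ob, n_g)
    log2[ob_rows[:, None], np.where(obese)[0][None, :]] += 0.15

    log2 = log2 + rng.normal(0.0, scenario.noise_sd, size=(n_g, n_s))

    abundance = pd.DataFrame(2.0 ** log2, index=genes, columns=samples)
    ct = pd.DataFrame(np.clip(34.0 - log2, 1.0, 44.0), index=genes, columns=samples)
    annot = pd.DataFrame(
        {
            "adiposity": np.where(obese, "obese", "lean"),
            "marker_class": np.where(marker_low, "low", "high"),
            "sex": sex,
        },
        index=pd.Index(samples, name="sample"),
    )
    return ExpressionExperiment(ct=ct, abundance=abundance, sample_annotations=annot)
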
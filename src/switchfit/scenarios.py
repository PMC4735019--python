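"""Scenario definitions for the synthetic cohort and expression generators.

A :class:`SwitchScenario` describes a two-component Gaussian trait mixture:
a dominant "lean" sub-population and a heavy ("on") sub-population entered
with probability ``pi_on`` (the penetrance, or obesity-on rate, of the heavy
state).  The heavy-component mean is expressed either as a multiplicative
shift (fraction increase over the lean mean, the natural parameterization
for mouse body weight and fat mass) or as an additive shift in trait units
(natural for BMI).

The preset registry encodes the published generative values for the mouse
knockout cohorts (Nnat paternal deletion: 26% on-rate, +40% body weight;
Peg3 paternal deletion: 20% on-rate, near-doubling of fat mass at N=80) and
for the NHANES childhood BMI surveys (lean means 15.81 / 15.87, heavy
fractions 12% / 38%, heavy component 4.5 BMI units above the lean mean).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

__all__ = [
    "SwitchScenario",
    "ExpressionScenario",
    "PRESETS",
    "IGN1_GENES",
    "HOUSEKEEPING_GENES",
    "get_preset",
]

#: Imprinted gene network 1: co-regulated, predominantly paternally
#: expressed genes implicated in body-size control.
IGN1_GENES = (
    "PLAGL1", "DLK1", "CDKN1C", "NNAT", "IGF2",
    "PEG3", "PPP1R9A", "NDN", "GRB10",
)

#: Housekeeping reference genes used for human qPCR normalization.
HOUSEKEEPING_GENES = ("TBP", "ACTB", "HPRT")


class ScenarioError(ValueError):
    """Raised when a scenario's fields violate its invariants."""


@dataclass(frozen=True)
class SwitchScenario:
    """Parameters of a two-component Gaussian trait mixture.

    Parameters
    ----------
    name : str
        Label attached to the generated cohort (also used as the era/site
        label by the two-era generator).
    n : int
        Number of mutant/surveyed individuals to draw.
    pi_on : float
        Mixing fraction of the heavy component, in [0, 1].
    mu_lean : float
        Lean-component mean, in trait units (grams or BMI).
    mult_shift : float, optional
        Heavy-component mean as a fractional increase over ``mu_lean``
        (0.40 means +40%).  Mutually exclusive with ``add_shift``.
    add_shift : float, optional
        Heavy-component mean as an additive offset in trait units.
    sigma_lean, sigma_heavy : float
        Component standard deviations, trait units.
    litter_size : float, optional
        Mean litter size; litters are drawn when this is set and a shared
        per-litter random effect may be added.
    litter_sd_frac : float
        Between-litter random-effect SD as a fraction of ``mu_lean``
        (0 disables the effect even when litters are assigned).
    seed : int, optional
        Default RNG seed used when the caller does not pass one.
    """

    name: str
    n: int
    pi_on: float
    mu_lean: float
    mult_shift: Optional[float] = None
    add_shift: Optional[float] = None
    sigma_lean: float = 1.0
    sigma_heavy: float = 1.0
    litter_size: Optional[float] = None
    litter_sd_frac: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi_on <= 1.0:
            raise ScenarioError(f"pi_on must be in [0, 1], got {self.pi_on}")
        if self.sigma_lean <= 0 or self.sigma_heavy <= 0:
            raise ScenarioError("component standard deviations must be positive")
        if self.n < 1:
            raise ScenarioError(f"n must be >= 1, got {self.n}")
        if (self.mult_shift is None) == (self.add_shift is None):
            raise ScenarioError(
                "exactly one of mult_shift / add_shift must be given"
            )
        if self.litter_size is not None and self.litter_size < 1:
            raise ScenarioError("litter_size must be >= 1 when given")
        if self.litter_sd_frac < 0:
            raise ScenarioError("litter_sd_frac must be >= 0")

    @property
    def mu_heavy(self) -> float:
        """Heavy-component mean in trait units."""
        if self.mult_shift is not None:
            return self.mu_lean * (1.0 + self.mult_shift)
        return self.mu_lean + self.add_shift  # type: ignore[operator]

    def with_overrides(self, **kwargs) -> "SwitchScenario":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ExpressionScenario:
    """Parameters of a synthetic gene x sample expression experiment.

    The generated cohort has two latent sample classes defined by a marker
    gene (low vs high expressors) and an independent obese/lean adiposity
    label.  Panel genes are suppressed only in samples that are both
    marker-low and obese; a slice of background genes carries a
    marker-class-correlated component so that the marker class, not
    adiposity, dominates sample-space variance.
    """

    n_samples: int = 40
    n_genes: int = 2000
    marker_gene: str = "TRIM28"
    panel_genes: tuple = IGN1_GENES
    housekeeping_genes: tuple = HOUSEKEEPING_GENES
    frac_marker_low: float = 0.5
    panel_suppression: float = 1.0  # mean log2 drop in marker-low obese samples
    frac_obese: float = 0.45       # 18 obese / 40 children
    noise_sd: float = 0.25         # residual SD of log2 expression
    marker_effect: float = 2.0     # log2 drop of the marker in the low class
    background_class_frac: float = 0.3   # fraction of background genes tied to marker class
    background_class_sd: float = 0.8     # SD of their class-linked log2 offsets
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("frac_marker_low", "frac_obese"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ScenarioError(f"{name} must be in [0, 1], got {v}")
        if set(self.panel_genes) & set(self.housekeeping_genes):
            raise ScenarioError("panel and housekeeping gene sets must be disjoint")
        if self.marker_gene in self.panel_genes or self.marker_gene in self.housekeeping_genes:
            raise ScenarioError("marker gene must not appear in panel or housekeeping sets")
        n_named = len(self.panel_genes) + len(self.housekeeping_genes) + 1
        if self.n_genes < n_named:
            raise ScenarioError(
                f"n_genes must be >= {n_named} to hold marker, panel and housekeeping genes"
            )
        if self.noise_sd < 0 or self.panel_suppression < 0:
            raise ScenarioError("noise_sd and panel_suppression must be >= 0")
        if self.n_samples < 4:
            raise ScenarioError("n_samples must be >= 4")


def _mouse_sigma(mu: float, cv: float = 0.08) -> float:
    # component SDs are not printed for the mouse cohorts; CV of 8% of the
    # component mean gives profiles matching the published histograms
    return cv * mu


PRESETS: dict[str, SwitchScenario] = {
    # Nnat paternal-deletion body weight: 26% on-rate, +40% body weight.
    "nnat": SwitchScenario(
        name="nnat",
        n=200,
        pi_on=0.26,
        mu_lean=30.0,
        mult_shift=0.40,
        sigma_lean=_mouse_sigma(30.0),
        sigma_heavy=_mouse_sigma(42.0),
    ),
    # Peg3 paternal-deletion fat mass: 20% on-rate, near-doubling, N=80.
    "peg3": SwitchScenario(
        name="peg3",
        n=80,
        pi_on=0.20,
        mu_lean=10.0,
        mult_shift=1.0,
        sigma_lean=_mouse_sigma(10.0),
        sigma_heavy=_mouse_sigma(20.0),
    ),
    # NHANES/NHES childhood BMI, males 6-11y, 1963-1994 surveys.
    "nhanes_child_1963": SwitchScenario(
        name="1963",
        n=4000,
        pi_on=0.12,
        mu_lean=15.81,
        add_shift=4.5,
        sigma_lean=1.3,
        sigma_heavy=3.0,
    ),
    # Continuous NHANES childhood BMI, males 6-11y, 1999-2012 surveys.
    "nhanes_child_1999": SwitchScenario(
        name="1999",
        n=4000,
        pi_on=0.38,
        mu_lean=15.87,
        add_shift=4.5,
        sigma_lean=1.3,
        sigma_heavy=3.0,
    ),
}


def get_preset(name: str, **overrides) -> SwitchScenario:
    """Look up a scenario preset by name, optionally overriding fields."""
    try:
        scenario = PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
    return scenario.with_overrides(**overrides) if overrides else scenario
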
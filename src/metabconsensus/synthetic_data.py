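"""Synthetic two-group serum metabolomics cohorts with planted effects.

The generator emulates a targeted serum-metabolomics case/control study:
40 pancreatic-cancer cases and 40 healthy controls measured on 206
metabolites split over two platforms — a commercial "kit" panel
(acylcarnitines, amino acids and biogenic amines, hexose, sphingomyelins,
glycerophospholipids; 181 analytes) and a custom "lipids" panel (bile
acids, fatty acids, sterols, glycerolipids, sphingolipids; 25 analytes).

Three discriminative metabolites are planted with the study's reported
effect sizes:

* **palmitic acid** — 20-fold lower in cases than in controls,
* **oleanolic acid** — 10-fold higher in cases,
* **D-sphingosine** — cases 0.24 ± 0.04 μM vs controls 0.09 ± 0.08 μM
  (mean ± SD, normal truncated at zero).

Null metabolites are drawn lognormal (the standard model for right-skewed
concentration data) with the configured concentration as the median and a
coefficient of variation of 30% by default. Each metabolite has its own
deterministic random substream derived from ``(seed, column index)`` so
values are stable under changes elsewhere in the panel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .dataset import MetabolomicsDataset

#: default within-group coefficient of variation of lognormal metabolites
DEFAULT_CV = 0.30

#: default fraction of missing values planted on non-discriminative metabolites
DEFAULT_MISSING_RATE = 0.05

PALMITIC = "palmitic acid"
OLEANOLIC = "oleanolic acid"
SPHINGOSINE = "D-sphingosine"


class ConfigurationError(ValueError):
    """Raised on an invalid cohort configuration."""


@dataclass(frozen=True)
class MetaboliteSpec:
    """Generative parameters of one metabolite.

    ``control_mean``/``control_sd`` describe the control group (for the
    lognormal model ``control_mean`` is the median and the ratio
    ``control_sd / control_mean`` sets the coefficient of variation).
    ``case_fold`` multiplies the control location to give the case
    location; 1.0 marks a null metabolite. If ``case_mean``/``case_sd``
    are given, both groups are instead drawn from zero-truncated normals
    with the stated moments (used for metabolites reported as mean ± SD).
    """

    name: str
    panel: str = "kit"
    control_mean: float = 1.0
    control_sd: float = 0.3
    case_fold: float = 1.0
    missing_rate: float = 0.0
    case_mean: float | None = None
    case_sd: float | None = None

    def __post_init__(self) -> None:
        if self.control_mean <= 0:
            raise ConfigurationError(f"{self.name}: control_mean must be > 0")
        if self.control_sd < 0:
            raise ConfigurationError(f"{self.name}: control_sd must be >= 0")
        if self.case_fold <= 0:
            raise ConfigurationError(f"{self.name}: case_fold must be > 0")
        if not 0 <= self.missing_rate < 1:
            raise ConfigurationError(f"{self.name}: missing_rate must be in [0, 1)")
        if (self.case_mean is None) != (self.case_sd is None):
            raise ConfigurationError(
                f"{self.name}: case_mean and case_sd must be given together"
            )

    @property
    def effective_fold(self) -> float:
        """Case/control location ratio, whichever parameterization is used."""
        if self.case_mean is not None:
            return self.case_mean / self.control_mean
        return self.case_fold

    @property
    def is_planted(self) -> bool:
        return self.effective_fold != 1.0


@dataclass(frozen=True)
class CohortConfig:
    """Design of a synthetic cohort.

    The default configuration reproduces the study design: 40 cases,
    40 controls, 206 metabolites with the three planted effects above.
    ``distribution`` selects the sampling model for null metabolites.
    """

    n_cases: int = 40
    n_controls: int = 40
    metabolites: tuple[MetaboliteSpec, ...] = field(default=None)  # type: ignore[assignment]
    distribution: str = "lognormal"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.metabolites is None:
            object.__setattr__(self, "metabolites", default_panel())
        object.__setattr__(self, "metabolites", tuple(self.metabolites))
        if self.n_cases < 1 or self.n_controls < 1:
            raise ConfigurationError("group sizes must be positive")
        if not self.metabolites:
            raise ConfigurationError("metabolite list must be non-empty")
        if self.distribution not in ("lognormal", "normal"):
            raise ConfigurationError(f"unknown distribution {self.distribution!r}")
        for panel in ("kit", "lipids"):
            names = [m.name for m in self.metabolites if m.panel == panel]
            if len(set(names)) != len(names):
                raise ConfigurationError(f"duplicate metabolite names in {panel} panel")


# ---------------------------------------------------------------------------
# default 206-metabolite panel
# ---------------------------------------------------------------------------

_ACYLCARNITINES = [
    "C0", "C2", "C3", "C3:1", "C3-OH", "C4", "C4:1", "C5", "C5:1",
    "C5:1-DC", "C5-DC (C6-OH)", "C5-M-DC", "C5-OH (C3-DC-M)", "C6 (C4:1-DC)",
    "C6:1", "C7-DC", "C8", "C9", "C10", "C10:1", "C10:2", "C12", "C12:1",
    "C12-DC", "C14", "C14:1", "C14:1-OH", "C14:2", "C14:2-OH", "C16",
    "C16:1", "C16:1-OH", "C16:2", "C16:2-OH", "C16-OH", "C18", "C18:1",
    "C18:1-OH", "C18:2", "C18:2-OH",
]

_AMINO_ACIDS = [
    "Ala", "Arg", "Asn", "Asp", "Cit", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Orn", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr",
    "Val",
]

_BIOGENIC_AMINES = [
    "ADMA", "alpha-AAA", "Carnosine", "Creatinine", "DOPA", "Dopamine",
    "Histamine", "Kynurenine", "Met-SO", "Nitro-Tyr", "OH-Pro", "PEA",
    "Putrescine", "Sarcosine", "SDMA", "Serotonin", "Spermidine",
    "Spermine", "Taurine",
]

_SPHINGOMYELINS = [
    "SM C16:0", "SM C16:1", "SM C18:0", "SM C18:1", "SM C20:2", "SM C24:0",
    "SM C24:1", "SM (OH) C14:1", "SM (OH) C16:1", "SM (OH) C22:1",
]

_LYSO_PC = [
    "14:0", "16:0", "16:1", "17:0", "18:0", "18:1", "18:2", "20:3", "20:4",
    "24:0", "26:0", "26:1", "28:0", "28:1",
]

_PC_AA = [
    "C24:0", "C26:0", "C28:1", "C30:0", "C32:0", "C32:1", "C32:2", "C32:3",
    "C34:1", "C34:2", "C34:3", "C34:4", "C36:0", "C36:1", "C36:2", "C36:3",
    "C36:4", "C36:5", "C36:6", "C38:0", "C38:3", "C38:4", "C38:5", "C38:6",
    "C40:1", "C40:2", "C40:3", "C40:4", "C40:5", "C40:6", "C42:0", "C42:1",
    "C42:2", "C42:4", "C42:5", "C42:6", "C44:5", "C44:6",
]

_PC_AE = [
    "C30:0", "C30:1", "C30:2", "C32:1", "C32:2", "C34:0", "C34:1", "C34:2",
    "C34:3", "C36:0", "C36:1", "C36:2", "C36:3", "C36:4", "C36:5", "C38:0",
    "C38:1", "C38:2", "C38:3", "C38:4", "C38:5", "C38:6", "C40:1", "C40:2",
    "C40:3", "C40:4", "C40:5", "C40:6", "C42:1", "C42:2", "C42:3", "C42:4",
    "C42:5", "C44:3", "C44:4", "C44:5", "C44:6", "C46:5",
]

# custom lipids panel: the consensus-table metabolites plus common serum lipids
_LIPIDS_NULL = [
    "Lysophosphatidylcholine C16:0", "Lysophosphatidylcholine C18:0",
    "Phosphatidylcholine (32:1)", "Cholesterol 5a,6a epoxide",
    "1,2-dioleoyl-sn-glycero-3-phospho-rac-glycerol", "Lanosterol",
    "Erucic acid", "Behenic acid", "Lignoceric acid", "Glyceryltrilinoleate",
    "1-monooleoyl-rac-glycerol", "Glycolithocholic acid",
    "Taurochenodeoxycholic acid", "Taurolithocholic acid",
    "Oleoyl-L-carnitine", "Glycochenodeoxycholic acid", "Cholic acid",
    "Chenodeoxycholic acid", "Deoxycholic acid", "Stearic acid",
    "Oleic acid", "Arachidonic acid",
]

# plausible serum concentration scales (μM) per metabolite class
_CLASS_SCALE = {
    "acylcarnitine": 0.2,
    "amino_acid": 120.0,
    "amine": 1.5,
    "hexose": 4500.0,
    "SM": 60.0,
    "PC": 25.0,
    "lysoPC": 40.0,
    "lipid": 15.0,
}


def _null(name: str, panel: str, scale: float) -> MetaboliteSpec:
    return MetaboliteSpec(
        name=name,
        panel=panel,
        control_mean=scale,
        control_sd=DEFAULT_CV * scale,
        missing_rate=DEFAULT_MISSING_RATE,
    )


def default_panel() -> tuple[MetaboliteSpec, ...]:
    """The 206-metabolite default panel (181 kit + 25 lipids)."""
    specs: list[MetaboliteSpec] = []
    for name in _ACYLCARNITINES:
        specs.append(_null(name, "kit", _CLASS_SCALE["acylcarnitine"]))
    for name in _AMINO_ACIDS:
        specs.append(_null(name, "kit", _CLASS_SCALE["amino_acid"]))
    for name in _BIOGENIC_AMINES:
        specs.append(_null(name, "kit", _CLASS_SCALE["amine"]))
    specs.append(_null("H1", "kit", _CLASS_SCALE["hexose"]))
    for name in _SPHINGOMYELINS:
        specs.append(_null(name, "kit", _CLASS_SCALE["SM"]))
    for tail in _LYSO_PC:
        specs.append(_null(f"lysoPC a {tail}", "kit", _CLASS_SCALE["lysoPC"]))
    for tail in _PC_AA:
        specs.append(_null(f"PC aa {tail}", "kit", _CLASS_SCALE["PC"]))
    for tail in _PC_AE:
        specs.append(_null(f"PC ae {tail}", "kit", _CLASS_SCALE["PC"]))

    specs.append(
        MetaboliteSpec(
            name=PALMITIC, panel="lipids", control_mean=270.0,
            control_sd=DEFAULT_CV * 270.0, case_fold=1 / 20,
        )
    )
    specs.append(
        MetaboliteSpec(
            name=OLEANOLIC, panel="lipids", control_mean=0.05,
            control_sd=DEFAULT_CV * 0.05, case_fold=10.0,
        )
    )
    specs.append(
        MetaboliteSpec(
            name=SPHINGOSINE, panel="lipids", control_mean=0.09,
            control_sd=0.08, case_mean=0.24, case_sd=0.04,
        )
    )
    for name in _LIPIDS_NULL:
        specs.append(_null(name, "lipids", _CLASS_SCALE["lipid"]))
    return tuple(specs)


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def _truncnorm(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    if sd == 0:
        return np.full(size, mean)
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def _sample_metabolite(
    spec: MetaboliteSpec, distribution: str, n_cases: int, n_controls: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Case values followed by control values for one metabolite."""
    if spec.case_mean is not None:
        cases = _truncnorm(rng, spec.case_mean, spec.case_sd, n_cases)
        controls = _truncnorm(rng, spec.control_mean, spec.control_sd, n_controls)
    elif distribution == "lognormal":
        cv = spec.control_sd / spec.control_mean
        sigma = math.sqrt(math.log1p(cv * cv))
        z = rng.standard_normal(n_cases + n_controls)
        medians = np.r_[
            np.full(n_cases, spec.control_mean * spec.case_fold),
            np.full(n_controls, spec.control_mean),
        ]
        return medians * np.exp(sigma * z)
    else:
        cases = _truncnorm(
            rng, spec.control_mean * spec.case_fold, spec.control_sd, n_cases
        )
        controls = _truncnorm(rng, spec.control_mean, spec.control_sd, n_controls)
    return np.r_[cases, controls]


def generate_cohort(config: CohortConfig) -> MetabolomicsDataset:
    """Draw a cohort; identical configs (including seed) give identical data.

    Cases occupy the first ``n_cases`` rows (label 1), controls the rest
    (label 0). Missing entries are drawn per metabolite as independent
    Bernoulli(``missing_rate``) after the values.
    """
    n = config.n_cases + config.n_controls
    p = len(config.metabolites)
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(p)

    values = np.empty((n, p))
    for j, spec in enumerate(config.metabolites):
        rng = np.random.default_rng(streams[j])
        values[:, j] = _sample_metabolite(
            spec, config.distribution, config.n_cases, config.n_controls, rng
        )
        if spec.missing_rate > 0:
            miss = rng.random(n) < spec.missing_rate
            values[miss, j] = np.nan

    width_t = len(str(config.n_cases))
    width_c = len(str(config.n_controls))
    sample_ids = [f"T{i + 1:0{width_t}d}" for i in range(config.n_cases)] + [
        f"C{i + 1:0{width_c}d}" for i in range(config.n_controls)
    ]
    labels = np.r_[np.ones(config.n_cases, int), np.zeros(config.n_controls, int)]
    return MetabolomicsDataset(
        sample_ids=sample_ids,
        labels=labels,
        metabolite_names=[m.name for m in config.metabolites],
        values=values,
        panel=np.array([m.panel for m in config.metabolites], dtype=object),
    )


def planted_truth(config: CohortConfig) -> list[tuple[str, str, float]]:
    """The planted discriminative metabolites of a configuration.

    Returns ``(name, direction, fold)`` triples where direction is ``"up"``
    if the case level exceeds the control level and the fold is expressed
    as a ratio > 1 in the stated direction (e.g. a metabolite 20-fold
    *lower* in cases is ``(name, "down", 20.0)``).
    """
    out = []
    for spec in config.metabolites:
        fold = spec.effective_fold
        if fold == 1.0:
            continue
        if fold > 1:
            out.append((spec.name, "up", fold))
        else:
            out.append((spec.name, "down", 1.0 / fold))
    return out


def null_config(**overrides) -> CohortConfig:
    """Default-shaped cohort with every planted effect switched off."""
    specs = tuple(
        replace(m, case_fold=1.0, case_mean=None, case_sd=None)
        for m in default_panel()
    )
    return CohortConfig(metabolites=specs, **overrides)
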
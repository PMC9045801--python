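"""Synthetic fungal-community generator with known ground truth.

Emulates a factorial deadwood-succession experiment: blocks x canopy
openness (open/closed) x deadwood species (beech/fir, on pure and mixed
plots), sampled yearly. Each taxon carries a ground-truth tree affinity
``pi_tree`` (1 = beech-only), a canopy affinity ``pi_canopy`` (1 =
closed-only), a Gaussian temporal occupancy window (peak ``mu``, width
``sigma``) and a base abundance scale, so downstream estimators of
specificity, succession time and occurrence duration can be checked
against a recoverable truth.

Randomness is organised as one child stream per operation, split from the
master seed, so stages can be re-run independently and reproducibly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import CountTable, SampleMetadata

__all__ = [
    "StudyDesign",
    "TaxonArchetype",
    "ChemRecord",
    "generate_design",
    "generate_taxa",
    "generate_community_counts",
    "generate_chemistry",
]


@dataclass(frozen=True)
class StudyDesign:
    """Factorial layout of the deadwood-succession experiment.

    Per block, canopy and year there are 8 composite samples: 2 beech from a
    pure-beech plot, 2 fir from a pure-fir plot, and 2 beech + 2 fir from a
    mixed plot. Every sample is of exactly one tree species; mixture is a
    plot-level flag. At the defaults this gives 64 samples per year and 384
    samples in total over 6 years.
    """

    n_blocks: int = 4
    n_years: int = 6

    @property
    def samples_per_year(self) -> int:
        return self.n_blocks * 2 * 8

    @property
    def total_samples(self) -> int:
        return self.samples_per_year * self.n_years


@dataclass(frozen=True)
class TaxonArchetype:
    """Ground truth of one synthetic taxon."""

    taxon_id: str
    pi_tree: float  # affinity for beech in [0, 1]; 1 = beech-only
    pi_canopy: float  # affinity for closed canopy in [0, 1]
    mu: float  # temporal peak (year)
    sigma: float  # temporal width (years), > 0
    base: float  # expected relative-abundance scale, > 0
    guild: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.pi_tree <= 1.0 and 0.0 <= self.pi_canopy <= 1.0):
            raise ValueError(f"{self.taxon_id}: affinities must lie in [0, 1]")
        if self.sigma <= 0:
            raise ValueError(f"{self.taxon_id}: sigma must be positive")
        if self.base <= 0:
            raise ValueError(f"{self.taxon_id}: base must be positive")


@dataclass(frozen=True)
class ChemRecord:
    """Wood-chemistry covariates of one sample."""

    sample_id: str
    pH: float
    ergosterol: float  # ug per g dry mass (fungal biomass proxy)
    C: float  # % dry mass
    N: float  # % dry mass
    moisture: float  # % fresh mass

    def __post_init__(self) -> None:
        if self.ergosterol < 0:
            raise ValueError("ergosterol must be non-negative")
        if not (0.0 <= self.moisture <= 100.0):
            raise ValueError("moisture must lie in [0, 100]")
        if not (0.0 < self.pH < 14.0):
            raise ValueError("pH must lie in (0, 14)")


_GUILD_POOL = (
    "saprotroph",
    "white_rot",
    "brown_rot",
    "soft_rot",
    "plant_pathogen",
    "ectomycorrhiza",
    "yeast",
    "endophyte",
)


def _child_rng(seed: int, label: str) -> np.random.Generator:
    """One deterministic stream per (seed, operation)."""
    root = np.random.SeedSequence(seed, spawn_key=(abs(hash_label(label)),))
    return np.random.default_rng(root)


def hash_label(label: str) -> int:
    # stable across processes (unlike builtin hash of str)
    h = 0
    for ch in label:
        h = (h * 131 + ord(ch)) % (2**31 - 1)
    return h


def generate_design(n_blocks: int = 4, n_years: int = 6, seed: int = 0) -> list[SampleMetadata]:
    """Lay out the factorial sampling design.

    Deterministic given its arguments (the seed is accepted for interface
    uniformity; the layout itself has no random component).
    """
    if n_blocks < 1 or n_years < 1:
        raise ValueError("n_blocks and n_years must be positive")
    records: list[SampleMetadata] = []
    for year in range(1, n_years + 1):
        for block in range(1, n_blocks + 1):
            for canopy in ("open", "closed"):
                # 2 beech on the pure-beech plot, 2 fir on the pure-fir plot,
                # 2 beech + 2 fir on the mixed plot
                layout = [
                    ("pure_beech", "beech", False),
                    ("pure_fir", "fir", False),
                    ("mixed", "beech", True),
                    ("mixed", "fir", True),
                ]
                for plot_kind, tree, mixture in layout:
                    plot = f"B{block}-{canopy}-{plot_kind}"
                    for rep in (1, 2):
                        sid = f"Y{year}_B{block}_{canopy}_{plot_kind}_{tree}_{rep}"
                        records.append(
                            SampleMetadata(
                                sample_id=sid,
                                tree=tree,
                                canopy=canopy,
                                block=block,
                                plot=plot,
                                mixture=mixture,
                                year=year,
                            )
                        )
    return records


def generate_taxa(
    n_taxa: int,
    specialist_fraction: float = 0.5,
    affinity_shape: tuple[float, float] = (2.0, 2.0),
    temporal_range: tuple[float, float] = (1.0, 6.0),
    seed: int = 0,
) -> list[TaxonArchetype]:
    """Draw taxon archetypes.

    A ``specialist_fraction`` of taxa are strict specialists (affinity 0 or
    1 with equal probability, independently for tree and canopy); the rest
    draw affinities from a Beta distribution with the given shape. Temporal
    peaks are uniform over ``temporal_range``; widths are log-uniform over
    [0.4, 2.5] years, spanning single-year spikes to multi-year residents;
    base abundances are log-normal so a few taxa dominate, as in real
    amplicon communities.
    """
    if n_taxa < 0:
        raise ValueError("n_taxa must be non-negative")
    if not (0.0 <= specialist_fraction <= 1.0):
        raise ValueError("specialist_fraction must lie in [0, 1]")
    a, b = affinity_shape
    if a <= 0 or b <= 0:
        raise ValueError("affinity_shape parameters must be positive")
    rng = _child_rng(seed, "taxa")
    taxa: list[TaxonArchetype] = []
    for i in range(n_taxa):
        affinities = []
        for _ in ("tree", "canopy"):
            if rng.random() < specialist_fraction:
                affinities.append(float(rng.integers(0, 2)))
            else:
                affinities.append(float(rng.beta(a, b)))
        mu = float(rng.uniform(*temporal_range))
        sigma = float(np.exp(rng.uniform(np.log(0.4), np.log(2.5))))
        base = float(rng.lognormal(mean=0.0, sigma=1.0))
        guild = str(rng.choice(_GUILD_POOL))
        taxa.append(
            TaxonArchetype(
                taxon_id=f"OTU{i + 1:04d}",
                pi_tree=affinities[0],
                pi_canopy=affinities[1],
                mu=mu,
                sigma=sigma,
                base=base,
                guild=guild,
            )
        )
    return taxa


def expected_abundance(taxon: TaxonArchetype, sample: SampleMetadata) -> float:
    """Expected (unnormalised) abundance of a taxon in a sample.

    base x tree weight x canopy weight x Gaussian temporal kernel; the tree
    weight is ``pi_tree`` on beech samples and ``1 - pi_tree`` on fir,
    analogously for canopy with closed as the reference level.
    """
    w_tree = taxon.pi_tree if sample.tree == "beech" else 1.0 - taxon.pi_tree
    w_canopy = taxon.pi_canopy if sample.canopy == "closed" else 1.0 - taxon.pi_canopy
    kernel = np.exp(-((sample.year - taxon.mu) ** 2) / (2.0 * taxon.sigma**2))
    return taxon.base * w_tree * w_canopy * kernel


def generate_community_counts(
    design: list[SampleMetadata],
    taxa: list[TaxonArchetype],
    depth: int = 2000,
    overdispersion: float = 0.01,
    seed: int = 0,
) -> tuple[CountTable, pd.DataFrame]:
    """Draw a count table from the archetypes under a Dirichlet-multinomial.

    For each sample the expected composition is perturbed by a Dirichlet
    draw with concentration ``expected proportions / overdispersion`` (so
    larger ``overdispersion`` means noisier compositions; taxa with zero
    expectation stay exactly zero), then ``depth`` reads are drawn
    multinomially. Every column therefore sums exactly to ``depth``.

    Returns the count table and a truth table recording each taxon's
    generative parameters.
    """
    if depth < 1:
        raise ValueError("depth must be at least 1")
    if overdispersion <= 0:
        raise ValueError("overdispersion must be positive")
    if not taxa:
        raise ValueError("taxa list is empty")
    rng = _child_rng(seed, "community")
    n_taxa, n_samples = len(taxa), len(design)
    expected = np.empty((n_taxa, n_samples))
    for j, sample in enumerate(design):
        for i, taxon in enumerate(taxa):
            expected[i, j] = expected_abundance(taxon, sample)
    counts = np.zeros((n_taxa, n_samples), dtype=np.int64)
    for j, sample in enumerate(design):
        total = expected[:, j].sum()
        if total <= 0:
            raise ValueError(f"sample {sample.sample_id}: all-zero expected composition")
        props = expected[:, j] / total
        alpha = props / overdispersion
        # gamma representation keeps structural zeros exactly zero
        gams = rng.gamma(shape=alpha)
        gsum = gams.sum()
        if gsum <= 0:  # pathological overdispersion; fall back to expectation
            probs = props
        else:
            probs = gams / gsum
        counts[:, j] = rng.multinomial(depth, probs)
    table = CountTable([t.taxon_id for t in taxa], [s.sample_id for s in design], counts)
    truth = pd.DataFrame(
        {
            "taxon_id": [t.taxon_id for t in taxa],
            "pi_tree": [t.pi_tree for t in taxa],
            "pi_canopy": [t.pi_canopy for t in taxa],
            "mu": [t.mu for t in taxa],
            "sigma": [t.sigma for t in taxa],
            "base": [t.base for t in taxa],
            "guild": [t.guild for t in taxa],
        }
    ).set_index("taxon_id")
    return table, truth


# Noiseless chemistry trajectories. pH falls linearly 5.3 -> 4.0 over the
# experiment for both species; ergosterol rises linearly, in beech over the
# whole run (31 -> 110 ug/g, years 1-6) and in fir only to year 5
# (10 -> 48 ug/g) after which it plateaus; N is species-specific and flat;
# C starts at C:N ratio x N and drifts up mildly; moisture rises with a
# beech offset.
_ERGO = {"beech": (31.0, 110.0, 6), "fir": (10.0, 48.0, 5)}
_N_PCT = {"beech": 0.27, "fir": 0.16}
_C_YEAR1 = {"beech": 154 * 0.27, "fir": 270 * 0.16}  # from year-1 C:N ratios


def chemistry_expectation(tree: str, year: int, n_years: int = 6) -> dict[str, float]:
    """Deterministic per-sample chemistry values before noise."""
    span = max(n_years - 1, 1)
    frac = (year - 1) / span
    pH = 5.3 + (4.0 - 5.3) * frac
    lo, hi, plateau_year = _ERGO[tree]
    ramp = min(year, plateau_year)
    ergosterol = lo + (hi - lo) * (ramp - 1) / max(plateau_year - 1, 1)
    N = _N_PCT[tree]
    C = _C_YEAR1[tree] + 2.0 * frac  # mild increase over decomposition
    moisture = (30.0 if tree == "fir" else 35.0) + 12.0 * frac
    return {"pH": pH, "ergosterol": ergosterol, "C": C, "N": N, "moisture": moisture}


def generate_chemistry(
    design: list[SampleMetadata],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[ChemRecord]:
    """Per-sample wood chemistry with optional relative Gaussian noise.

    ``noise_sd`` is a *relative* standard deviation (fraction of each
    variable's deterministic value) so one knob scales sensibly across pH,
    percentages and ergosterol concentrations. Values are clipped to their
    physical bounds. At ``noise_sd = 0`` the output is deterministic.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    n_years = max(s.year for s in design)
    rng = _child_rng(seed, "chemistry")
    records = []
    for sample in design:
        base = chemistry_expectation(sample.tree, sample.year, n_years)
        vals = {}
        for key, value in base.items():
            noisy = value * (1.0 + noise_sd * rng.standard_normal()) if noise_sd else value
            vals[key] = noisy
        vals["pH"] = float(np.clip(vals["pH"], 1e-6, 14 - 1e-6))
        vals["ergosterol"] = float(max(vals["ergosterol"], 0.0))
        vals["moisture"] = float(np.clip(vals["moisture"], 0.0, 100.0))
        vals["C"] = float(np.clip(vals["C"], 0.0, 100.0))
        vals["N"] = float(max(vals["N"], 0.0))
        records.append(ChemRecord(sample_id=sample.sample_id, **vals))
    return records


def chemistry_frame(records: list[ChemRecord]) -> pd.DataFrame:
    frame = pd.DataFrame(
        [(r.sample_id, r.pH, r.ergosterol, r.C, r.N, r.moisture) for r in records],
        columns=["sample_id", "pH", "ergosterol", "C", "N", "moisture"],
    )
    return frame.set_index("sample_id")
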
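"""Synthetic competition-assay data with the study's variance structure.

The generator emulates a blocked dual-label competition experiment: in each
of 5 blocks, every combination of 3 focal strains x 2 GFP-marked competitor
strains x 3 counting methods is replicated 24 times.  Biological variation
is placed on the log-CI (log-odds) scale — the scale on which dispersion is
least coupled to the mean — as a block effect plus an among-plate deviation;
the counted sample then adds binomial sampling of the focal fraction and
method-specific counting error:

* false-positive worms (debris / E. coli clumps read as worms), a Poisson
  excess on the total count;
* false-negative GFP calls (a fluorescent worm read as non-fluorescent),
  binomial thinning of the GFP count — this inflates the focal frequency p;
* symmetric relative miscount noise on the total.

The per-method error rates are order-of-magnitude guesses (no published
estimates exist); their defaults matter only for qualitative bias-direction
checks, not for any quantitative target.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .metrics import OBSERVATION_COLUMNS
from .render import RenderConfig, render_well_image  # re-export

__all__ = [
    "MethodError",
    "SimulationConfig",
    "simulate_assay",
    "apply_method_error",
    "simulate_split_samples",
    "simulate_recounts",
    "full_design_config",
    "RenderConfig",
    "render_well_image",
]


@dataclass(frozen=True)
class MethodError:
    """Counting-error model of one method.

    fp_worm_rate: expected extra (non-worm) objects per true worm counted.
    fn_gfp_rate: probability a GFP worm is read as non-fluorescent.
    miscount_sd: SD of relative noise on the total count.
    """

    fp_worm_rate: float = 0.0
    fn_gfp_rate: float = 0.0
    miscount_sd: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fn_gfp_rate <= 1.0:
            raise ValueError("fn_gfp_rate must lie in [0, 1]")
        if self.fp_worm_rate < 0 or self.miscount_sd < 0:
            raise ValueError("rates must be non-negative")


#: order-of-magnitude guesses; see docs/methods.md
DEFAULT_METHOD_ERROR = {
    "by_eye": MethodError(fp_worm_rate=0.002, fn_gfp_rate=0.002, miscount_sd=0.005),
    "cellprofiler": MethodError(fp_worm_rate=0.02, fn_gfp_rate=0.02, miscount_sd=0.01),
    "sorter": MethodError(fp_worm_rate=0.01, fn_gfp_rate=0.005, miscount_sd=0.02),
}

#: default mean log CI per focal x competitor cell: wild-type focal strains
#: tend to out-compete GFP-marked competitors, so all means are >= 0
#: (focal frequencies ~0.5-0.8, matching the magnitude of real assays).
DEFAULT_MU_LOGCI = {
    ("N2", "ST2"): 1.0,
    ("N2", "VP604"): 1.4,
    ("PB306", "ST2"): 0.5,
    ("PB306", "VP604"): 0.9,
    ("CB4856", "ST2"): 0.0,
    ("CB4856", "VP604"): 0.4,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design and variance parameters of the synthetic assay."""

    n_blocks: int = 5
    focal_strains: tuple[str, ...] = ("N2", "PB306", "CB4856")
    competitor_strains: tuple[str, ...] = ("ST2", "VP604")
    methods: tuple[str, ...] = ("by_eye", "cellprofiler", "sorter")
    reps_per_cell: int = 24
    mu_logci: dict = field(default_factory=lambda: dict(DEFAULT_MU_LOGCI))
    sigma_block: float = 0.3
    sigma_bio: float = 1.0
    worms_per_sample: float = 176.0
    split_worms_per_sample: float = 694.0
    split_mu_logci: float = 0.2
    method_error: dict = field(
        default_factory=lambda: dict(DEFAULT_METHOD_ERROR)
    )
    split_fraction: float = 0.25
    drop_by_eye_block: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.reps_per_cell < 1:
            raise ValueError("n_blocks and reps_per_cell must be >= 1")
        if self.sigma_block < 0 or self.sigma_bio < 0:
            raise ValueError("variance components must be non-negative")
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must lie in (0, 1)")
        if self.worms_per_sample <= 0 or self.split_worms_per_sample <= 0:
            raise ValueError("worms_per_sample must be positive")
        for (f, c) in (
            (f, c)
            for f in self.focal_strains
            for c in self.competitor_strains
        ):
            if (f, c) not in self.mu_logci:
                raise ValueError(f"mu_logci missing cell ({f}, {c})")
        for m in self.methods:
            if m not in self.method_error:
                raise ValueError(f"method_error missing method {m}")


def full_design_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The full study design: 5 blocks x 18 combinations x 24 replicates,
    with by-eye counts absent from one block."""
    return replace(SimulationConfig(seed=seed, drop_by_eye_block=True), **overrides)


def apply_method_error(
    n_total_true: np.ndarray,
    n_gfp_true: np.ndarray,
    err: MethodError,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Corrupt true plate counts with one method's counting-error model.

    ``n_gfp_obs ~ Binomial(n_gfp_true, 1 - fn_gfp_rate)``;
    ``n_total_obs = n_total_true + Poisson(fp_rate * n_total_true) +
    round(Normal(0, miscount_sd * n_total_true))``, floored at ``n_gfp_obs``.
    """
    n_total_true = np.asarray(n_total_true, dtype=np.int64)
    n_gfp_true = np.asarray(n_gfp_true, dtype=np.int64)
    n_gfp_obs = rng.binomial(n_gfp_true, 1.0 - err.fn_gfp_rate)
    extra = rng.poisson(err.fp_worm_rate * n_total_true)
    noise = np.rint(
        rng.normal(0.0, err.miscount_sd * np.maximum(n_total_true, 1))
    ).astype(np.int64)
    n_total_obs = np.maximum(n_total_true + extra + noise, n_gfp_obs)
    return n_total_obs, n_gfp_obs


def simulate_assay(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the full blocked assay.

    Per plate: ``logCI_true = mu_logci[cell] + block_effect +
    Normal(0, sigma_bio)``; ``p_true = expit(logCI_true)``; the total count
    is Poisson around ``worms_per_sample`` (min 1), the focal count binomial,
    and the observed counts pass through the method's error model.

    Returns the observation table (canonical schema) and a truth table with
    the per-plate latent values for recovery tests.
    """
    rng = np.random.default_rng(config.seed)
    blocks = [f"B{b + 1}" for b in range(config.n_blocks)]
    block_eff = dict(
        zip(blocks, rng.normal(0.0, config.sigma_block, size=len(blocks)))
    )
    obs_rows = []
    truth_rows = []
    for b in blocks:
        for f in config.focal_strains:
            for c in config.competitor_strains:
                for m in config.methods:
                    if (
                        config.drop_by_eye_block
                        and m == "by_eye"
                        and b == blocks[0]
                    ):
                        continue
                    mu = config.mu_logci[(f, c)]
                    R = config.reps_per_cell
                    logci = (
                        mu
                        + block_eff[b]
                        + rng.normal(0.0, config.sigma_bio, size=R)
                    )
                    p_true = expit(logci)
                    n_tot = np.maximum(
                        rng.poisson(config.worms_per_sample, size=R), 1
                    )
                    n_focal = rng.binomial(n_tot, p_true)
                    n_gfp_true = n_tot - n_focal
                    n_tot_obs, n_gfp_obs = apply_method_error(
                        n_tot, n_gfp_true, config.method_error[m], rng
                    )
                    for r in range(R):
                        rid = f"r{r + 1}"
                        obs_rows.append(
                            (b, f, c, m, rid, int(n_tot_obs[r]), int(n_gfp_obs[r]))
                        )
                        truth_rows.append(
                            {
                                "block_id": b,
                                "focal_strain": f,
                                "competitor_strain": c,
                                "method": m,
                                "replicate_id": rid,
                                "block_effect": block_eff[b],
                                "log_ci_true": logci[r],
                                "p_true": p_true[r],
                                "n_total_true": int(n_tot[r]),
                                "n_gfp_true": int(n_gfp_true[r]),
                            }
                        )
    obs = pd.DataFrame(obs_rows, columns=OBSERVATION_COLUMNS)
    truth = pd.DataFrame(truth_rows)
    return obs, truth


def simulate_recounts(
    config: SimulationConfig,
    n_images: int,
    recount_sd: float = 0.005,
    fn_gfp_rate: float = 0.002,
) -> pd.DataFrame:
    """Simulate two independent counting passes over the same images.

    Each image holds a fixed true census (no sampling between passes: the
    image does not change); each pass adds independent relative miscount
    noise on the total and a small chance of missing a GFP call, emulating
    a human re-counting the same image weeks later.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    rng = np.random.default_rng(config.seed)
    n_tot = np.maximum(rng.poisson(config.worms_per_sample, size=n_images), 1)
    p_true = expit(rng.normal(config.split_mu_logci, config.sigma_bio, n_images))
    n_gfp = n_tot - rng.binomial(n_tot, p_true)
    err = MethodError(fp_worm_rate=0.0, fn_gfp_rate=fn_gfp_rate, miscount_sd=recount_sd)
    t1, g1 = apply_method_error(n_tot, n_gfp, err, rng)
    t2, g2 = apply_method_error(n_tot, n_gfp, err, rng)
    return pd.DataFrame(
        {
            "image_id": [f"img{i + 1}" for i in range(n_images)],
            "n_total_1": t1,
            "n_gfp_1": g1,
            "n_total_2": t2,
            "n_gfp_2": g2,
        }
    )


def simulate_split_samples(
    config: SimulationConfig, n_wells: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate sorter split-sample wells.

    Each well's suspension holds ``n_total ~ Poisson(split_worms_per_sample)``
    worms with focal frequency drawn logit-normal around
    ``split_mu_logci``; a volumetric split allocates each worm independently
    to the small aliquot with probability ``split_fraction`` (so the aliquot
    size is binomial and its composition hypergeometric given the size).
    """
    if n_wells < 1:
        raise ValueError("n_wells must be >= 1")
    rng = np.random.default_rng(config.seed)
    n_tot = np.maximum(rng.poisson(config.split_worms_per_sample, size=n_wells), 2)
    logci = rng.normal(config.split_mu_logci, config.sigma_bio, size=n_wells)
    p_true = expit(logci)
    n_focal = rng.binomial(n_tot, p_true)
    n_small = np.clip(rng.binomial(n_tot, config.split_fraction), 1, n_tot - 1)
    n_focal_small = rng.hypergeometric(n_focal, n_tot - n_focal, n_small)
    records = pd.DataFrame(
        {
            "well_id": [f"w{i + 1}" for i in range(n_wells)],
            "n_total_small": n_small,
            "n_gfp_small": n_small - n_focal_small,
            "n_total_large": n_tot - n_small,
            "n_gfp_large": (n_tot - n_focal) - (n_small - n_focal_small),
        }
    )
    truth = pd.DataFrame(
        {
            "well_id": records["well_id"],
            "p_true": p_true,
            "log_ci_true": logci,
            "n_total": n_tot,
            "n_focal": n_focal,
        }
    )
    return records, truth
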
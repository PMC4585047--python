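"""Synthetic c-Fos count tables with known factorial means and known latent networks.

The generator emulates a 2 × 2 factorial immediate-early-gene study
(treatment ``MA``/``SAL`` × phase ``light``/``dark``, ``n_per_cell`` animals
per cell) over a panel of brain regions.  Counts are produced by a latent
Gaussian copula: for each animal a multivariate-normal vector is drawn with
the animal's treatment-group correlation matrix, then each coordinate is
pushed through a lognormal marginal whose mean is the region's configured
cell mean and whose coefficient of variation is the ``dispersion``
parameter, and finally rounded to the nearest integer.  This yields
right-skewed, nonnegative, overdispersed counts carrying an arbitrary
imposed inter-regional correlation structure.

The lognormal transform attenuates the latent (copula) correlation; the
closed-form attenuated target is available as
:func:`attenuated_correlation`, so recovery tests can compare realized
Pearson correlations against an exact expectation rather than the raw
latent value.

Named cell-mean presets reproduce each of the five factorial activation
patterns (treatment-only, time-only, interaction, treatment-and-time,
null), and :func:`study_config` assembles the full 17-region study layout
including an optional MA-specific "hub" enhancement of VMH connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import GenerationError, SpecificationError
from .sample_table import PHASES, TREATMENTS

#: The 17-region panel: hypothalamic, thalamic, amygdalar, hippocampal,
#: cortical and striatal regions quantified in the motivating study design.
REGIONS: Tuple[str, ...] = (
    "SCN", "PVN", "PVT", "CEA", "BLA", "MEA", "DG", "CA1", "CA3",
    "ILC", "ARC", "VMH", "DMH", "BNST", "CIN", "NACc", "NACs",
)

#: Maximum tolerated per-entry change when projecting a target correlation
#: matrix to the PSD cone; larger repairs would silently change the truth
#: the simulation is supposed to embody.
PSD_REPAIR_TOLERANCE = 0.05


# ---------------------------------------------------------------------------
# latent correlation structure
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HubSpec:
    """A hub enhancement: region ``hub`` couples to each of ``partners`` at ``r``."""

    hub: int
    partners: Tuple[int, ...]
    r: float


def repair_psd(
    matrix: np.ndarray,
    max_change: float = PSD_REPAIR_TOLERANCE,
    eig_tol: float = 1e-10,
) -> Tuple[np.ndarray, float]:
    """Project a symmetric matrix to the PSD cone, renormalizing the diagonal.

    Negative eigenvalues are clipped to zero and the diagonal rescaled back
    to one.  Returns ``(repaired, max_abs_entry_change)``; raises
    :class:`GenerationError` if any entry moves by more than ``max_change``.
    Matrices already PSD (within ``eig_tol``) are returned unchanged with a
    reported change of 0.
    """
    matrix = np.asarray(matrix, dtype=float)
    w, v = np.linalg.eigh(matrix)
    if w.min() >= -eig_tol:
        return matrix, 0.0
    a = (v * np.clip(w, 0.0, None)) @ v.T
    d = np.sqrt(np.diag(a))
    if (d == 0).any():
        raise GenerationError("PSD repair collapsed a diagonal entry to zero")
    a = a / np.outer(d, d)
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 1.0)
    delta = float(np.abs(a - matrix).max())
    if delta > max_change:
        raise GenerationError(
            f"PSD repair would change an entry by {delta:.4f} "
            f"(> {max_change}); the requested correlation structure is infeasible"
        )
    return a, delta


def build_latent_correlation(
    region_count: int,
    base_r: float,
    hub_spec: Optional[HubSpec] = None,
    max_repair: float = PSD_REPAIR_TOLERANCE,
) -> Tuple[np.ndarray, float]:
    """Build an equicorrelated region network with an optional hub.

    All off-diagonal entries equal ``base_r``; if ``hub_spec`` is given, the
    hub–partner entries are set to ``hub_spec.r`` instead.  The result is
    projected to the nearest PSD matrix if needed.

    Returns ``(matrix, psd_repair_delta)`` where the delta is the maximum
    absolute entry change introduced by the projection (0 when none was
    needed).
    """
    if region_count < 2:
        raise SpecificationError("region_count must be at least 2")
    if not -1.0 < base_r < 1.0:
        raise SpecificationError(f"base_r must lie in (-1, 1); got {base_r}")
    c = np.full((region_count, region_count), float(base_r))
    np.fill_diagonal(c, 1.0)
    if hub_spec is not None:
        if not -1.0 < hub_spec.r < 1.0:
            raise SpecificationError(f"hub correlation must lie in (-1, 1); got {hub_spec.r}")
        ids = (hub_spec.hub, *hub_spec.partners)
        for i in ids:
            if not 0 <= i < region_count:
                raise SpecificationError(
                    f"hub/partner index {i} out of range for {region_count} regions"
                )
        if hub_spec.hub in hub_spec.partners:
            raise SpecificationError("hub region cannot be its own partner")
        for p in hub_spec.partners:
            c[hub_spec.hub, p] = c[p, hub_spec.hub] = hub_spec.r
    return repair_psd(c, max_change=max_repair)


# ---------------------------------------------------------------------------
# marginal transform
# ---------------------------------------------------------------------------

def _lognormal_params(mean: float, cv: float) -> Tuple[float, float]:
    """(mu, sigma) of a lognormal with the given mean and coefficient of variation."""
    sigma2 = np.log1p(cv * cv)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def attenuated_correlation(rho: float, cv_a: float, cv_b: float) -> float:
    """Pearson correlation implied on the count scale by latent correlation ``rho``.

    For two lognormal marginals with sigmas ``s_a``, ``s_b`` driven by
    Gaussians correlated at ``rho``, the product-moment correlation is

        (exp(rho * s_a * s_b) - 1) / sqrt((exp(s_a^2) - 1) (exp(s_b^2) - 1))

    which shrinks toward zero as dispersion grows.  In the limit of zero
    dispersion the attenuation vanishes and ``rho`` is returned.
    Integer rounding of the counts is neglected (second-order for means well
    above 1).
    """
    if cv_a == 0.0 or cv_b == 0.0:
        return float(rho)
    sa2 = np.log1p(cv_a * cv_a)
    sb2 = np.log1p(cv_b * cv_b)
    return float(
        np.expm1(rho * np.sqrt(sa2 * sb2)) / np.sqrt(np.expm1(sa2) * np.expm1(sb2))
    )


# ---------------------------------------------------------------------------
# generator configuration
# ---------------------------------------------------------------------------

@dataclass
class GeneratorConfig:
    """Full specification of a synthetic factorial c-Fos study.

    Parameters
    ----------
    region_names
        Ordered region identifiers.
    n_per_cell
        Animals per treatment × phase cell (the study design used 10).
    cell_means
        Per region, a 2 × 2 array of expected counts indexed
        ``[treatment, phase]`` in the order ``(MA, SAL)`` × ``(light, dark)``.
    dispersion
        Coefficient of variation of counts on the latent scale (≥ 0;
        0 gives noiseless rounded cell means).
    latent_corr
        Per treatment group, the target latent (copula) region × region
        correlation matrix.
    seed
        Master RNG seed; it deterministically spawns independent substreams
        per group and per animal.
    hub_spec
        Optional record of a hub enhancement baked into ``latent_corr``
        (kept for provenance; not re-applied at simulation time).
    """

    region_names: Sequence[str]
    n_per_cell: int
    cell_means: Mapping[str, np.ndarray]
    dispersion: float
    latent_corr: Mapping[str, np.ndarray]
    seed: int
    hub_spec: Optional[Tuple[str, Tuple[str, ...], float]] = None

    def __post_init__(self) -> None:
        self.region_names = tuple(self.region_names)
        if len(set(self.region_names)) != len(self.region_names):
            raise SpecificationError("region names must be unique")
        if self.n_per_cell < 2:
            raise SpecificationError("n_per_cell must be at least 2")
        if self.dispersion < 0:
            raise SpecificationError("dispersion (CV) must be nonnegative")
        for region in self.region_names:
            if region not in self.cell_means:
                raise SpecificationError(f"cell_means missing region {region!r}")
            m = np.asarray(self.cell_means[region], dtype=float)
            if m.shape != (2, 2):
                raise SpecificationError(
                    f"cell_means[{region!r}] must be 2x2 (treatment x phase)"
                )
            if (m < 0).any():
                raise SpecificationError(f"cell_means[{region!r}] has negative entries")
        r = len(self.region_names)
        for group in TREATMENTS:
            if group not in self.latent_corr:
                raise SpecificationError(f"latent_corr missing group {group!r}")
            c = np.asarray(self.latent_corr[group], dtype=float)
            if c.shape != (r, r):
                raise SpecificationError(f"latent_corr[{group!r}] must be {r}x{r}")
            if not np.allclose(c, c.T, atol=1e-12):
                raise SpecificationError(f"latent_corr[{group!r}] is not symmetric")
            if not np.allclose(np.diag(c), 1.0, atol=1e-12):
                raise SpecificationError(f"latent_corr[{group!r}] diagonal must be 1")
            if (np.abs(c) > 1 + 1e-12).any():
                raise SpecificationError(f"latent_corr[{group!r}] has entries outside [-1, 1]")


def simulate_counts(config: GeneratorConfig) -> pd.DataFrame:
    """Draw a synthetic sample table from a :class:`GeneratorConfig`.

    The table has ``4 * n_per_cell`` rows ordered MA-light, MA-dark,
    SAL-light, SAL-dark, one column per region, and is byte-identical across
    calls with the same config and seed.
    """
    regions = list(config.region_names)
    r = len(regions)
    means = np.stack(
        [np.asarray(config.cell_means[reg], dtype=float) for reg in regions]
    )  # (R, 2, 2): region x treatment x phase
    cv = float(config.dispersion)
    sigma2 = np.log1p(cv * cv)
    sigma = np.sqrt(sigma2)

    factors: Dict[str, np.ndarray] = {}
    for group in TREATMENTS:
        c, _ = repair_psd(np.asarray(config.latent_corr[group], dtype=float))
        w, v = np.linalg.eigh(c)
        factors[group] = v * np.sqrt(np.clip(w, 0.0, None))

    master = np.random.SeedSequence(config.seed)
    group_seqs = master.spawn(len(TREATMENTS))

    rows = []
    for ti, (group, gseq) in enumerate(zip(TREATMENTS, group_seqs)):
        animal_seqs = gseq.spawn(2 * config.n_per_cell)
        k = 0
        for pi, phase in enumerate(PHASES):
            for j in range(config.n_per_cell):
                rng = np.random.default_rng(animal_seqs[k])
                k += 1
                z = factors[group] @ rng.standard_normal(r)
                m = means[:, ti, pi]
                if cv == 0.0:
                    counts = np.rint(m)
                else:
                    counts = np.where(
                        m > 0,
                        np.rint(np.exp(np.log(np.where(m > 0, m, 1.0)) - sigma2 / 2.0 + sigma * z)),
                        0.0,
                    )
                rows.append(
                    {
                        "animal_id": f"{group}_{phase}_{j + 1:03d}",
                        "treatment": group,
                        "phase": phase,
                        **{reg: counts[i] for i, reg in enumerate(regions)},
                    }
                )
    return pd.DataFrame(rows, columns=["animal_id", "treatment", "phase", *regions])


def write_fixture(table: pd.DataFrame, path) -> None:
    """Write a sample table as CSV readable by :func:`fosnet.io.read_sample_table`."""
    from .io import write_sample_table

    write_sample_table(table, path)


# ---------------------------------------------------------------------------
# study presets
# ---------------------------------------------------------------------------

def pattern_presets() -> Dict[str, np.ndarray]:
    """Named 2 × 2 cell-mean layouts, one per factorial activation pattern.

    Arrays are indexed ``[treatment, phase]`` with rows (MA, SAL) and
    columns (light, dark):

    - ``treatment_only``: drug raises counts equally in both phases.
    - ``time_only``: day > night regardless of drug (SCN-like).
    - ``interaction``: drug effect mostly confined to the light phase, plus
      a marginal time effect (PVN-like).
    - ``interaction_no_time``: crossing layout whose phase marginals cancel,
      so only treatment and interaction are real (PVT/ARC-like).
    - ``treatment_and_time``: additive drug and phase effects.
    - ``null``: flat means everywhere.
    """
    return {
        "treatment_only": np.array([[100.0, 100.0], [40.0, 40.0]]),
        "time_only": np.array([[120.0, 40.0], [120.0, 40.0]]),
        "interaction": np.array([[150.0, 60.0], [40.0, 40.0]]),
        "interaction_no_time": np.array([[120.0, 60.0], [30.0, 90.0]]),
        "treatment_and_time": np.array([[120.0, 80.0], [70.0, 30.0]]),
        "null": np.array([[50.0, 50.0], [50.0, 50.0]]),
    }


#: Which preset drives each region in the 17-region study layout.
STUDY_PRESET_BY_REGION: Dict[str, str] = {
    "ILC": "treatment_only", "CEA": "treatment_only", "BNST": "treatment_only",
    "CA1": "treatment_only", "CIN": "treatment_only", "NACc": "treatment_only",
    "SCN": "time_only", "VMH": "time_only", "DMH": "time_only",
    "PVN": "interaction", "PVT": "interaction_no_time", "ARC": "interaction_no_time",
    "CA3": "treatment_and_time", "NACs": "treatment_and_time",
    "MEA": "null", "BLA": "null", "DG": "null",
}


def study_cell_means() -> Dict[str, np.ndarray]:
    """Cell means for the full 17-region panel, one preset per region."""
    presets = pattern_presets()
    return {reg: presets[STUDY_PRESET_BY_REGION[reg]].copy() for reg in REGIONS}


def reference_pattern_flags() -> pd.DataFrame:
    """Reported two-way-ANOVA significance flags for the 17-region panel.

    Boolean columns ``treatment``, ``time``, ``interaction`` per region:
    the published significance profile of each region in the
    methamphetamine light/dark c-Fos study that this package's workflow
    reproduces.  These flags are the canonical worked example for
    :func:`fosnet.anova.pattern_from_flags`.
    """
    yes_t = {"ILC", "CEA", "BNST", "CA1", "CIN", "NACc",
             "PVN", "PVT", "ARC", "CA3", "NACs"}
    yes_time = {"SCN", "VMH", "DMH", "PVN", "CA3", "NACs"}
    yes_inter = {"PVN", "PVT", "ARC"}
    return pd.DataFrame(
        {
            "treatment": [reg in yes_t for reg in REGIONS],
            "time": [reg in yes_time for reg in REGIONS],
            "interaction": [reg in yes_inter for reg in REGIONS],
        },
        index=pd.Index(REGIONS, name="region"),
    )


def flat_cell_means(region_names: Sequence[str], mean: float = 60.0) -> Dict[str, np.ndarray]:
    """Identical cell means everywhere: no treatment, time, or interaction effects.

    Useful for isolating connectivity behaviour from mean structure."""
    return {reg: np.full((2, 2), float(mean)) for reg in region_names}


def study_config(
    n_per_cell: int = 10,
    dispersion: float = 0.3,
    base_r: float = 0.2,
    hub_region: Optional[str] = "VMH",
    hub_partners: Sequence[str] = ("PVN", "BLA", "MEA"),
    hub_r: float = 0.7,
    seed: int = 0,
) -> GeneratorConfig:
    """Assemble the default 17-region study configuration.

    All regions share a weak baseline latent coupling ``base_r`` in both
    groups; if ``hub_region`` is given, its edges to ``hub_partners`` are
    raised to ``hub_r`` in the MA group only, emulating a drug-specific
    connectivity hub.  Pass ``hub_region=None`` for identical networks in
    both groups (the null configuration used for calibration).
    """
    idx = {reg: i for i, reg in enumerate(REGIONS)}
    hub = None
    hub_record = None
    if hub_region is not None:
        for name in (hub_region, *hub_partners):
            if name not in idx:
                raise SpecificationError(f"unknown region {name!r} in hub specification")
        hub = HubSpec(idx[hub_region], tuple(idx[p] for p in hub_partners), hub_r)
        hub_record = (hub_region, tuple(hub_partners), hub_r)
    sal_corr, _ = build_latent_correlation(len(REGIONS), base_r)
    ma_corr, _ = build_latent_correlation(len(REGIONS), base_r, hub)
    return GeneratorConfig(
        region_names=REGIONS,
        n_per_cell=n_per_cell,
        cell_means=study_cell_means(),
        dispersion=dispersion,
        latent_corr={"MA": ma_corr, "SAL": sal_corr},
        seed=seed,
        hub_spec=hub_record,
    )
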
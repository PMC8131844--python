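"""Synthetic isopycnic CsCl gradients with partial isotope labeling.

The simulator builds a ground-truth community (per-OTU relative abundance,
G+C content, label status, atom-fraction excess of ¹³C/¹⁵N), places each
OTU's DNA in the gradient as a Gaussian band, splits the gradient into
equal-width density fractions, and draws per-fraction sequencing counts from
a multinomial at fixed depth.  Because the generator records which OTUs were
labeled, downstream detection can be scored for sensitivity and realized
false-discovery proportion — something a real experiment never permits.

Band placement follows the classical CsCl density relations for DNA:
the native buoyant density rises linearly with G+C fraction
(``rho = 1.660 + 0.098 * GC`` g/ml) and full heavy-isotope substitution adds
a fixed density increment (0.036 g/ml for ¹³C, 0.016 g/ml for ¹⁵N), scaled
here by the DNA atom-fraction excess actually reached.  All four constants
are configuration, not code.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "GradientConfig",
    "IsotopeDensityModel",
    "DEFAULT_DENSITY_MODEL",
    "SCENARIO_PRESETS",
    "scenario_preset",
    "native_bd",
    "label_shift",
    "band_profile",
    "fraction_centers",
    "make_community",
    "expected_fraction_profiles",
    "simulate_experiment",
    "write_simulation",
]

#: Substrate-labeling presets: attainable DNA atom-fraction-excess caps for
#: labeled OTUs, matching the labeling degree of each substrate.
SCENARIO_PRESETS: dict[str, dict[str, float]] = {
    "PAOM": {"afe_13C": 0.15, "afe_15N": 0.09},
    "protein": {"afe_13C": 0.18, "afe_15N": 0.07},
    "acetate": {"afe_13C": 0.50, "afe_15N": 0.0},
}

_TAXONOMY_POOL = [
    "Bacteria;Planctomycetes;Phycisphaerae;MSBL9;uncultured;uncultured",
    "Bacteria;Planctomycetes;Phycisphaerae;Phycisphaerales;Phycisphaeraceae;uncultured",
    "Bacteria;Planctomycetes;Phycisphaerae;CCM11a;uncultured;uncultured",
    "Bacteria;Chloroflexi;Anaerolineae;Anaerolineales;Anaerolineaceae;uncultured",
    "Bacteria;Chloroflexi;Dehalococcoidia;Dehalococcoidales;uncultured;uncultured",
    "Bacteria;Chloroflexi;JG30-KF-CM66;uncultured;uncultured;uncultured",
    "Bacteria;Proteobacteria;Deltaproteobacteria;Desulfobacterales;Desulfobacteraceae;uncultured",
    "Bacteria;Bacteroidetes;Bacteroidia;Bacteroidales;uncultured;uncultured",
    "Bacteria;Firmicutes;Clostridia;Clostridiales;uncultured;uncultured",
    "Bacteria;Actinobacteria;Acidimicrobiia;Microtrichales;uncultured;uncultured",
    "Bacteria;Epsilonbacteraeota;Campylobacteria;Campylobacterales;Sulfurovaceae;Sulfurovum",
    "Archaea;Crenarchaeota;Bathyarchaeia;uncultured;uncultured;uncultured",
    "Archaea;Nanoarchaeota;Woesearchaeia;uncultured;uncultured;uncultured",
]


@dataclass(frozen=True)
class GradientConfig:
    """Geometry and sampling depth of one simulated CsCl gradient.

    Defaults reproduce the study design: 12 equal fractions spanning
    1.674–1.737 g/ml collected from a gradient spun at a mean CsCl density
    of 1.725 g/ml.
    """

    bd_min: float = 1.674  # g/ml, lightest collected density
    bd_max: float = 1.737  # g/ml, heaviest collected density
    n_fractions: int = 12
    band_sd: float = 0.006  # g/ml, Gaussian band width per OTU
    depth_per_fraction: int = 30_000  # reads sequenced per fraction
    mean_density: float = 1.725  # g/ml, loading density of the CsCl solution
    carryover: float = 0.02  # mass fraction of each OTU smeared uniformly over fractions

    def __post_init__(self) -> None:
        if not self.bd_min < self.bd_max:
            raise ValueError("bd_min must be < bd_max")
        if self.n_fractions < 2:
            raise ValueError("need at least 2 fractions")
        if self.band_sd <= 0:
            raise ValueError("band_sd must be positive")
        if self.depth_per_fraction < 1:
            raise ValueError("depth_per_fraction must be >= 1")
        if not 0 <= self.carryover < 1:
            raise ValueError("carryover must lie in [0, 1)")


@dataclass(frozen=True)
class IsotopeDensityModel:
    """Linear GC→density relation and full-labeling density increments."""

    native_intercept: float = 1.660  # g/ml at GC = 0
    native_slope: float = 0.098  # g/ml per unit GC fraction
    shift_13C: float = 0.036  # g/ml at 100% 13C substitution
    shift_15N: float = 0.016  # g/ml at 100% 15N substitution


DEFAULT_DENSITY_MODEL = IsotopeDensityModel()


def scenario_preset(name: str) -> dict[str, float]:
    """Return the atom-fraction-excess caps for a named substrate scenario."""
    try:
        return dict(SCENARIO_PRESETS[name])
    except KeyError:
        raise ValueError(
            f"unknown scenario preset {name!r}; valid presets: {sorted(SCENARIO_PRESETS)}"
        ) from None


def native_bd(gc, model: IsotopeDensityModel = DEFAULT_DENSITY_MODEL):
    """Native (unlabeled) buoyant density of DNA with the given G+C fraction."""
    gc = np.asarray(gc, dtype=float)
    if np.any((gc < 0) | (gc > 1)):
        raise ValueError("gc must lie in [0, 1]")
    bd = model.native_intercept + model.native_slope * gc
    return float(bd) if bd.ndim == 0 else bd


def label_shift(afe_13C, afe_15N, model: IsotopeDensityModel = DEFAULT_DENSITY_MODEL):
    """Density increment from partial isotope incorporation.

    Linear in each atom-fraction excess; full substitution recovers the
    configured per-isotope shifts.
    """
    a13 = np.asarray(afe_13C, dtype=float)
    a15 = np.asarray(afe_15N, dtype=float)
    if np.any((a13 < 0) | (a13 > 1)) or np.any((a15 < 0) | (a15 > 1)):
        raise ValueError("atom fraction excess must lie in [0, 1]")
    shift = model.shift_13C * a13 + model.shift_15N * a15
    return float(shift) if shift.ndim == 0 else shift


def _bin_edges(config: GradientConfig) -> np.ndarray:
    return np.linspace(config.bd_min, config.bd_max, config.n_fractions + 1)


def fraction_centers(config: GradientConfig) -> np.ndarray:
    """Bin-center densities in fraction order (index 1 = heaviest), g/ml."""
    edges = _bin_edges(config)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return centers[::-1].copy()  # heaviest first, matching collection from the tube bottom


def band_profile(center_bd: float, config: GradientConfig) -> np.ndarray:
    """Per-fraction mass fractions of a Gaussian DNA band.

    The Gaussian (mean ``center_bd``, sd ``config.band_sd``) is integrated
    over the equal-width density bins spanning [bd_min, bd_max] and
    renormalized over the bins, so the returned vector sums to 1.  Order
    follows :func:`fraction_centers` (heaviest fraction first).
    """
    if config.band_sd <= 0:
        raise ValueError("band_sd must be positive")
    edges = _bin_edges(config)
    cdf = norm.cdf(edges, loc=center_bd, scale=config.band_sd)
    mass = np.diff(cdf)
    total = mass.sum()
    if total <= 0:
        # Band centered far outside the collected range: all recovered DNA
        # sits in the nearest edge fraction.
        mass = np.zeros(config.n_fractions)
        mass[0 if center_bd <= config.bd_min else -1] = 1.0
    else:
        mass = mass / total
    return mass[::-1].copy()


def band_mean_density(
    center_bd: float,
    config: GradientConfig,
    depth: int | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Count-weighted mean collected density of one OTU's DNA band, g/ml.

    Weights are the band's per-fraction mass shares at the fraction-center
    densities.  With ``depth`` given, the shares are estimated by a
    multinomial draw of that many molecules (Monte-Carlo); otherwise the
    exact expectation is returned.  Note the result saturates when the band
    center leaves the collected density range.
    """
    mass = band_profile(center_bd, config)
    if depth is not None:
        rng = np.random.default_rng() if rng is None else rng
        mass = rng.multinomial(depth, mass) / depth
    return float(np.dot(fraction_centers(config), mass))


def make_community(
    n_otus: int,
    frac_labeled: float,
    seed: int | np.random.Generator,
    preset: str | None = None,
    afe_13C: float | None = None,
    afe_15N: float | None = None,
    assimilation_efficiency: float = 1.0,
    gc_range: tuple[float, float] = (0.26, 0.40),
    abundance_sigma: float = 1.5,
) -> pd.DataFrame:
    """Draw a ground-truth community.

    Relative abundances are lognormal (``sigma`` on the log scale) and
    normalized to sum to 1; G+C fractions are uniform on ``gc_range``;
    a random ``frac_labeled`` share of OTUs is flagged labeled and given the
    scenario's atom-fraction-excess caps scaled by ``assimilation_efficiency``
    (dilution of the label by unlabeled carbon/nitrogen).  Taxonomy strings
    are drawn from a small pool of sediment lineages.
    """
    if not 0 <= frac_labeled <= 1:
        raise ValueError("frac_labeled must lie in [0, 1]")
    if not 0 <= assimilation_efficiency <= 1:
        raise ValueError("assimilation_efficiency must lie in [0, 1]")
    if preset is not None:
        caps = scenario_preset(preset)
        afe_13C = caps["afe_13C"] if afe_13C is None else afe_13C
        afe_15N = caps["afe_15N"] if afe_15N is None else afe_15N
    afe_13C = 0.5 if afe_13C is None else afe_13C
    afe_15N = 0.0 if afe_15N is None else afe_15N

    rng = np.random.default_rng(seed)
    rel = rng.lognormal(mean=0.0, sigma=abundance_sigma, size=n_otus)
    rel = rel / rel.sum()
    gc = rng.uniform(gc_range[0], gc_range[1], size=n_otus)
    n_labeled = int(round(frac_labeled * n_otus))
    labeled_idx = rng.choice(n_otus, size=n_labeled, replace=False)
    is_labeled = np.zeros(n_otus, dtype=bool)
    is_labeled[labeled_idx] = True
    taxonomy = rng.choice(_TAXONOMY_POOL, size=n_otus)

    truth = pd.DataFrame(
        {
            "otu_id": [f"OTU_{i:04d}" for i in range(n_otus)],
            "rel_abundance": rel,
            "gc": gc,
            "is_labeled": is_labeled,
            "afe_13C": np.where(is_labeled, afe_13C * assimilation_efficiency, 0.0),
            "afe_15N": np.where(is_labeled, afe_15N * assimilation_efficiency, 0.0),
            "taxonomy": taxonomy,
        }
    )
    return truth


def _validate_truth(truth: pd.DataFrame) -> None:
    if truth.empty:
        raise ValueError("truth table is empty")
    if truth["otu_id"].duplicated().any():
        dups = truth.loc[truth["otu_id"].duplicated(), "otu_id"].tolist()
        raise ValueError(f"duplicate otu_ids in truth table: {dups[:5]}")
    total = truth["rel_abundance"].sum()
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"rel_abundance must sum to 1, got {total}")
    unlabeled = ~truth["is_labeled"].astype(bool)
    if ((truth.loc[unlabeled, "afe_13C"] != 0) | (truth.loc[unlabeled, "afe_15N"] != 0)).any():
        raise ValueError("unlabeled OTUs must have zero atom fraction excess")


def expected_fraction_profiles(
    truth: pd.DataFrame,
    config: GradientConfig,
    labeled_gradient: bool,
    density_model: IsotopeDensityModel = DEFAULT_DENSITY_MODEL,
    rel_abundance: np.ndarray | None = None,
) -> pd.DataFrame:
    """Noise-free per-fraction community proportions (OTUs × fractions).

    Each OTU's band center is its native GC-dependent density plus, in a
    labeled gradient only, the label-induced shift of labeled OTUs.  A
    ``config.carryover`` share of every OTU's mass is spread uniformly over
    the fractions, emulating the low-level smear of all taxa found in every
    fraction of real gradients (diffusion, sheared fragments, wall
    contamination) — the background the paired control gradient corrects
    for.  Columns are fraction indices 1..n (1 = heaviest); each column sums
    to 1.
    """
    _validate_truth(truth)
    rel = truth["rel_abundance"].to_numpy() if rel_abundance is None else np.asarray(rel_abundance)
    centers = native_bd(truth["gc"].to_numpy(), density_model)
    if labeled_gradient:
        centers = centers + np.where(
            truth["is_labeled"].to_numpy(dtype=bool),
            label_shift(truth["afe_13C"].to_numpy(), truth["afe_15N"].to_numpy(), density_model),
            0.0,
        )
    bands = np.vstack([band_profile(c, config) for c in centers])  # OTUs x fractions
    if config.carryover > 0:
        bands = (1.0 - config.carryover) * bands + config.carryover / config.n_fractions
    weighted = bands * rel[:, None]
    col_tot = weighted.sum(axis=0)
    col_tot[col_tot == 0] = 1.0
    props = weighted / col_tot
    return pd.DataFrame(
        props, index=truth["otu_id"].to_numpy(), columns=np.arange(1, config.n_fractions + 1)
    )


def simulate_experiment(
    truth: pd.DataFrame,
    config: GradientConfig,
    timepoints: Sequence[float],
    seed: int | np.random.Generator,
    treatment: str = "substrate",
    density_model: IsotopeDensityModel = DEFAULT_DENSITY_MODEL,
    composition_jitter: float = 0.0,
    depth_jitter_sigma: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate paired labeled/control gradients at each timepoint.

    Returns ``(counts, metadata, truth)``: an integer OTU × fraction-sample
    count table, a fraction metadata table (sample_id, treatment, isotope,
    timepoint_days, fraction_index, buoyant_density), and the truth record.

    ``composition_jitter`` > 0 perturbs the control slurry's community with a
    Dirichlet draw of that concentration (larger = milder perturbation),
    emulating between-slurry compositional drift — the failure mode the
    light-window control criterion of the detector guards against.
    ``depth_jitter_sigma`` > 0 draws per-fraction depths lognormally around
    ``depth_per_fraction``.  A fixed seed makes the output reproducible.
    """
    _validate_truth(truth)
    rng = np.random.default_rng(seed)

    count_cols: dict[str, np.ndarray] = {}
    meta_rows: list[dict] = []
    centers = fraction_centers(config)

    for tp in timepoints:
        for isotope in ("labeled", "control"):
            rel = truth["rel_abundance"].to_numpy()
            if isotope == "control" and composition_jitter > 0:
                alpha = np.maximum(rel * composition_jitter, 1e-8)
                rel = rng.dirichlet(alpha)
            props = expected_fraction_profiles(
                truth, config, labeled_gradient=(isotope == "labeled"),
                density_model=density_model, rel_abundance=rel,
            ).to_numpy()
            for f_idx in range(config.n_fractions):
                depth = config.depth_per_fraction
                if depth_jitter_sigma > 0:
                    depth = max(1, int(round(depth * rng.lognormal(0.0, depth_jitter_sigma))))
                p = props[:, f_idx]
                p = p / p.sum() if p.sum() > 0 else np.full(len(p), 1.0 / len(p))
                sample_id = f"{treatment}_{isotope}_T{tp:g}_F{f_idx + 1:02d}"
                count_cols[sample_id] = rng.multinomial(depth, p)
                meta_rows.append(
                    {
                        "sample_id": sample_id,
                        "treatment": treatment,
                        "isotope": isotope,
                        "timepoint_days": tp,
                        "fraction_index": f_idx + 1,
                        "buoyant_density": centers[f_idx],
                    }
                )

    counts = pd.DataFrame(count_cols, index=truth["otu_id"].to_numpy())
    counts.index.name = "otu_id"
    metadata = pd.DataFrame(meta_rows)
    return counts, metadata, truth.copy()


def write_simulation(
    out_dir: str | Path,
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    truth: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write counts.tsv / fractions.tsv / taxonomy.tsv (/ truth.tsv) to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    counts_path = out / "counts.tsv"
    counts.to_csv(counts_path, sep="\t")
    paths["counts"] = counts_path
    meta_path = out / "fractions.tsv"
    metadata.to_csv(meta_path, sep="\t", index=False)
    paths["fractions"] = meta_path
    if truth is not None:
        tax_path = out / "taxonomy.tsv"
        truth[["otu_id", "taxonomy"]].rename(columns={"taxonomy": "lineage"}).to_csv(
            tax_path, sep="\t", index=False
        )
        paths["taxonomy"] = tax_path
        truth_path = out / "truth.tsv"
        truth[["otu_id", "is_labeled", "gc", "afe_13C", "afe_15N", "rel_abundance"]].to_csv(
            truth_path, sep="\t", index=False
        )
        paths["truth"] = truth_path
    return paths
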
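"""Synthetic two-group neonatal cohorts of paired SC/FC data.

The generator emulates the statistical structure the downstream
analysis assumes, in place of access-restricted neonatal imaging data:

- a shared node set split into left/right hemispheres;
- a ground-truth structural backbone with stochastic-block structure
  (denser within-hemisphere than between), from which per-subject
  directed streamline-count matrices are drawn with high cross-subject
  consistency (negative-binomial counts around shared per-edge rates,
  plus a sparse spurious-streamline floor);
- a preterm-group backbone obtained from the full-term backbone by
  degree-preserving rewiring of a fraction ``rewire_fraction`` of its
  edges, so edge *identity* differs between groups while degree
  sequences are preserved;
- a multiplicative linear effect of gestational age at birth on
  within-hemisphere edge rates (slope ``ga_eff_slope`` per week);
- ROI time series drawn from a zero-mean multivariate normal whose
  covariance mixes the subject's own (row-normalized, symmetrized)
  structural connectome with white noise, scaled by a per-group
  functional-strength factor, so derived correlation matrices contain
  negative entries and carry a group difference in FC strength.

All randomness flows from a single integer seed through a documented
seed-sequence splitting scheme, so cohorts are bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .thresholding import round_half_up

__all__ = ["SimConfig", "SubjectRecord", "Cohort", "generate_cohort", "write_cohort"]

GA_REF_WEEKS = 40.0  # GA centering point for the planted weight effect


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort generator.

    Defaults encode the study conditions the analysis is designed to
    detect: a planted group difference in SC edge architecture
    (``rewire_fraction``), globally weaker functional coupling in the
    preterm group (``fc_strength_pt < fc_strength_ft``), and a positive
    linear association between gestational age and within-hemisphere
    structural edge weight (``ga_eff_slope``).
    """

    n_nodes: int = 20
    hemisphere_split: float = 0.5
    n_ft: int = 20
    n_pt: int = 20
    n_timepoints: int = 150
    sc_backbone_density: float = 0.25
    rewire_fraction: float = 0.5
    fc_coupling: float = 0.2
    fc_strength_ft: float = 1.0
    fc_strength_pt: float = 0.3
    ga_eff_slope: float = 0.02
    count_mean: float = 120.0
    count_dispersion: float = 2.0
    count_noise_rate: float = 0.3
    ts_noise_sd: float = 1.0
    within_hemisphere_odds: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        fractions = {
            "hemisphere_split": self.hemisphere_split,
            "sc_backbone_density": self.sc_backbone_density,
            "rewire_fraction": self.rewire_fraction,
            "fc_coupling": self.fc_coupling,
        }
        for name, v in fractions.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_ft < 2 or self.n_pt < 2:
            raise ValueError("subject counts must be >= 2")
        if self.n_timepoints < 10:
            raise ValueError("n_timepoints must be >= 10")
        if self.n_nodes < 4:
            raise ValueError("need at least 4 nodes")
        if self.fc_strength_ft < 0 or self.fc_strength_pt < 0:
            raise ValueError("FC strength factors must be nonnegative")
        if self.count_mean <= 0 or self.count_dispersion <= 0:
            raise ValueError("count parameters must be positive")
        if self.ts_noise_sd <= 0:
            raise ValueError("ts_noise_sd must be positive")

    @classmethod
    def exchangeable_null(cls, **overrides) -> "SimConfig":
        """Config under which the two groups' SC and FC generative
        distributions are identical (no rewiring, equal strength factors,
        no GA effect on weights)."""
        base = dict(
            rewire_fraction=0.0,
            fc_strength_pt=cls.fc_strength_ft,
            ga_eff_slope=0.0,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class SubjectRecord:
    """One subject's covariates driving regression and permutation labels."""

    subject_id: str
    group: str  # "FT" or "PT"
    ga_birth: float  # weeks
    pma_scan: float  # weeks
    sex: str  # "F" or "M"
    birth_weight: float | None = None  # kg

    def __post_init__(self) -> None:
        if self.group not in ("FT", "PT"):
            raise ValueError("group must be 'FT' or 'PT'")
        if not (22.0 <= self.ga_birth <= 44.0):
            raise ValueError(f"ga_birth {self.ga_birth} outside [22, 44] weeks")
        if self.group == "FT" and self.ga_birth < 37.0:
            raise ValueError("FT subjects must have ga_birth >= 37 weeks")
        if self.group == "PT" and self.ga_birth >= 37.0:
            raise ValueError("PT subjects must have ga_birth < 37 weeks")


@dataclass
class Cohort:
    """Generated inputs for one synthetic study."""

    config: SimConfig
    subjects: list[SubjectRecord]
    node_labels: list[str]
    hemisphere: list[str]
    roi_sizes: pd.Series  # node label -> size
    sc_forward: dict[str, np.ndarray]  # subject_id -> N x N int counts
    sc_reverse: dict[str, np.ndarray]
    timeseries: dict[str, np.ndarray]  # subject_id -> T x N
    backbones: dict[str, np.ndarray] = field(default_factory=dict)
    log: dict = field(default_factory=dict)

    def subject_ids(self, group: str | None = None) -> list[str]:
        return [
            s.subject_id for s in self.subjects if group is None or s.group == group
        ]

    def metadata_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(s) for s in self.subjects])


def _draw_covariates(config: SimConfig, rng: np.random.Generator) -> list[SubjectRecord]:
    """Sample per-subject covariates.

    FT gestational age ~ Normal(39.5, 1.2) truncated to [37, 44]; PT
    gestational age ~ Uniform(23, 36.9).  Postmenstrual age at scan is
    a term-equivalent window for both groups; birth weight grows
    roughly linearly with gestational age.
    """
    records = []
    a, b = (37.0 - 39.5) / 1.2, (44.0 - 39.5) / 1.2
    ga_ft = stats.truncnorm.rvs(
        a, b, loc=39.5, scale=1.2, size=config.n_ft, random_state=rng
    )
    ga_pt = rng.uniform(23.0, 36.9, size=config.n_pt)
    ap, bp = (37.0 - 40.5) / 1.8, (44.0 - 40.5) / 1.8
    pma = stats.truncnorm.rvs(
        ap, bp, loc=40.5, scale=1.8, size=config.n_ft + config.n_pt, random_state=rng
    )
    sexes = rng.choice(["F", "M"], size=config.n_ft + config.n_pt)
    gas = np.concatenate([ga_ft, ga_pt])
    groups = ["FT"] * config.n_ft + ["PT"] * config.n_pt
    bw = np.clip(
        0.19 * (gas - 22.0) + rng.normal(0.0, 0.3, size=gas.size), 0.4, 5.0
    )
    for i, (g, ga) in enumerate(zip(groups, gas)):
        records.append(
            SubjectRecord(
                subject_id=f"sub-{i:03d}",
                group=g,
                ga_birth=float(round(ga, 3)),
                pma_scan=float(round(pma[i], 3)),
                sex=str(sexes[i]),
                birth_weight=float(round(bw[i], 3)),
            )
        )
    return records


def _sample_backbone(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Ground-truth FT backbone adjacency with two hemisphere blocks.

    Exactly ``round_half_up(density * M)`` edges are selected by
    weighted sampling without replacement, with within-hemisphere pairs
    ``within_hemisphere_odds`` times more likely than interhemispheric
    pairs (Efraimidis-Stirling keys), reproducing denser short-range
    connectivity alongside interhemispheric edges.
    """
    n = config.n_nodes
    n_left = round_half_up(config.hemisphere_split * n)
    hemi = np.array(["L"] * n_left + ["R"] * (n - n_left))
    iu = np.triu_indices(n, 1)
    m = iu[0].size
    n_edges = round_half_up(config.sc_backbone_density * m)
    within = hemi[iu[0]] == hemi[iu[1]]
    w = np.where(within, config.within_hemisphere_odds, 1.0)
    u = rng.uniform(size=m)
    keys = u ** (1.0 / w)
    chosen = np.argsort(-keys)[:n_edges]
    adj = np.zeros((n, n), dtype=bool)
    adj[iu[0][chosen], iu[1][chosen]] = True
    return adj | adj.T


def _rewire_backbone(
    adj: np.ndarray, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Degree-preserving double-edge-swap rewiring of ``fraction`` of edges."""
    if fraction == 0:
        return adj.copy()
    g = nx.from_numpy_array(adj.astype(int))
    m = g.number_of_edges()
    nswap = round_half_up(fraction * m / 2.0)
    if nswap > 0:
        try:
            nx.double_edge_swap(
                g, nswap=nswap, max_tries=nswap * 1000,
                seed=np.random.RandomState(int(rng.integers(0, 2**31 - 1))),
            )
        except nx.NetworkXAlgorithmError:
            # tiny/dense graphs can run out of admissible swaps; completed
            # swaps are kept, so the rewired fraction is merely smaller
            warnings.warn("double-edge swap budget exhausted; partial rewiring")
    return nx.to_numpy_array(g, dtype=bool)


def _row_normalized_sym(w: np.ndarray) -> np.ndarray:
    rs = w.sum(axis=1, keepdims=True)
    rs[rs == 0] = 1.0
    p = w / rs
    return (p + p.T) / 2.0


def generate_cohort(config: SimConfig) -> Cohort:
    """Generate a full two-group cohort.

    Deterministic given ``config.seed``.  The seed is split by
    ``numpy.random.SeedSequence`` into independent streams for
    (covariates, backbone, edge rates, ROI sizes, per-subject data), so
    e.g. changing the number of time points does not perturb the
    covariate draw.
    """
    ss = np.random.SeedSequence(config.seed)
    s_cov, s_bb, s_rates, s_sizes, s_subj = ss.spawn(5)
    rng_cov = np.random.default_rng(s_cov)
    rng_bb = np.random.default_rng(s_bb)
    rng_rates = np.random.default_rng(s_rates)
    rng_sizes = np.random.default_rng(s_sizes)

    n = config.n_nodes
    n_left = round_half_up(config.hemisphere_split * n)
    hemisphere = ["L"] * n_left + ["R"] * (n - n_left)
    node_labels = [f"roi_{h}{i:03d}" for i, h in enumerate(hemisphere)]

    subjects = _draw_covariates(config, rng_cov)

    backbone_ft = _sample_backbone(config, rng_bb)
    backbone_pt = _rewire_backbone(backbone_ft, config.rewire_fraction, rng_bb)

    # per-pair base rates, drawn once for ALL node pairs so shared edges
    # of the two backbones carry identical rates (exchangeability at
    # rewire_fraction = 0)
    log_rates = rng_rates.normal(np.log(config.count_mean), 0.4, size=(n, n))
    base_rates = np.exp((log_rates + log_rates.T) / 2.0)

    roi_sizes = pd.Series(
        np.round(np.exp(rng_sizes.normal(np.log(300.0), 0.3, size=n))).astype(int),
        index=node_labels,
        name="size",
    )

    hemi_arr = np.array(hemisphere)
    within_mask = hemi_arr[:, None] == hemi_arr[None, :]

    sc_forward: dict[str, np.ndarray] = {}
    sc_reverse: dict[str, np.ndarray] = {}
    timeseries: dict[str, np.ndarray] = {}
    repaired: list[str] = []

    subj_seeds = s_subj.spawn(len(subjects))
    for rec, child in zip(subjects, subj_seeds):
        rng = np.random.default_rng(child)
        backbone = backbone_ft if rec.group == "FT" else backbone_pt
        ga_factor = np.where(
            within_mask,
            np.maximum(0.0, 1.0 + config.ga_eff_slope * (rec.ga_birth - GA_REF_WEEKS)),
            1.0,
        )
        rates = np.where(backbone, base_rates * ga_factor, 0.0)
        np.fill_diagonal(rates, 0.0)

        fwd = _draw_counts(rates, config, rng)
        rev = _draw_counts(rates, config, rng)
        sc_forward[rec.subject_id] = fwd
        sc_reverse[rec.subject_id] = rev

        strength = (
            config.fc_strength_ft if rec.group == "FT" else config.fc_strength_pt
        )
        sym_counts = (fwd + rev.T) / 2.0
        sym_counts = (sym_counts + sym_counts.T) / 2.0
        s_hat = _row_normalized_sym(sym_counts)
        sigma = (
            config.fc_coupling * strength * s_hat
            + (1.0 - config.fc_coupling) * config.ts_noise_sd**2 * np.eye(n)
        )
        min_eig = float(np.linalg.eigvalsh(sigma).min())
        if min_eig < 1e-8:
            sigma = sigma + (1e-8 - min_eig + 1e-12) * np.eye(n)
            repaired.append(rec.subject_id)
        chol = np.linalg.cholesky(sigma)
        z = rng.standard_normal((config.n_timepoints, n))
        timeseries[rec.subject_id] = z @ chol.T

    return Cohort(
        config=config,
        subjects=subjects,
        node_labels=node_labels,
        hemisphere=hemisphere,
        roi_sizes=roi_sizes,
        sc_forward=sc_forward,
        sc_reverse=sc_reverse,
        timeseries=timeseries,
        backbones={"FT": backbone_ft, "PT": backbone_pt},
        log={"sigma_repaired": repaired},
    )


def _draw_counts(
    rates: np.ndarray, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Directed streamline counts: negative binomial around the edge
    rates plus a sparse Poisson floor of spurious streamlines."""
    n = rates.shape[0]
    disp = config.count_dispersion
    counts = np.zeros((n, n), dtype=np.int64)
    pos = rates > 0
    if np.any(pos):
        p = disp / (disp + rates[pos])
        counts[pos] = rng.negative_binomial(disp, p)
    counts += rng.poisson(config.count_noise_rate, size=(n, n))
    np.fill_diagonal(counts, 0)
    return counts


def write_cohort(cohort: Cohort, directory: str | Path) -> None:
    """Serialize a cohort as plain CSV files.

    Layout: ``metadata.csv``, ``nodes.csv`` (label, hemisphere),
    ``roi_sizes.csv``, and per subject ``ts_<id>.csv`` (T rows, node
    labels as header) plus ``sc_<id>_forward.csv`` / ``sc_<id>_reverse.csv``
    (labeled square count matrices).  Round-trips losslessly through
    :func:`neomux.io.read_cohort`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cohort.metadata_frame().to_csv(directory / "metadata.csv", index=False)
    pd.DataFrame(
        {"node_label": cohort.node_labels, "hemisphere": cohort.hemisphere}
    ).to_csv(directory / "nodes.csv", index=False)
    cohort.roi_sizes.rename_axis("node_label").reset_index().to_csv(
        directory / "roi_sizes.csv", index=False
    )
    for sid in cohort.subject_ids():
        pd.DataFrame(cohort.timeseries[sid], columns=cohort.node_labels).to_csv(
            directory / f"ts_{sid}.csv", index=False
        )
        for tag, mats in (("forward", cohort.sc_forward), ("reverse", cohort.sc_reverse)):
            pd.DataFrame(
                mats[sid], index=cohort.node_labels, columns=cohort.node_labels
            ).to_csv(directory / f"sc_{sid}_{tag}.csv")
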
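"""End-to-end orchestration of the three-hypothesis workflow.

Stage order: connectome construction -> thresholding -> metric tables ->
H1 permutation report (group edge overlap, consistency thresholding) ->
H2 regression (efficiency on GA x hemisphere, proportional
thresholding) -> H3 multiplex metrics + regression -> exploratory
strength t-tests and AUC models.  Consistency thresholding is used
exclusively for H1 and proportional thresholding exclusively for
H2/H3; the run log records this mode mapping, tie-break/degeneracy
events and excluded density levels so they are auditable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .connectome import strength_score
from .inference import permutation_profile
from .io import build_cohort_connectomes
from .metrics import efficiency_profiles, hemisphere_subnetwork
from .multiplex import MultiplexPair, multiplex_profiles
from .regression import fit_auc_models, fit_density_models, strength_ttest
from .simulate import Cohort, SimConfig, generate_cohort
from .thresholding import DensityGrid, make_density_grid, proportional_threshold

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline", "render_summary"]


@dataclass(frozen=True)
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    density_start: float = 0.05
    density_stop: float = 0.70
    density_step: float = 0.05
    n_perm: int = 10_000
    alpha: float = 0.05
    seed: int = 0
    neg_policy: str = "zero"
    max_density: float = 0.5
    degeneracy_min_unique: int = 20

    def grid(self) -> DensityGrid:
        return make_density_grid(
            self.density_start, self.density_stop, self.density_step
        )

    def config_hash(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha1(blob.encode()).hexdigest()[:10]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        return cls(sim=sim, **raw)


@dataclass
class PipelineReport:
    config: PipelineConfig
    h1: pd.DataFrame  # permutation report, both modalities
    efficiency: pd.DataFrame  # long-format metric profiles
    h2: pd.DataFrame  # per-density regressions on efficiency
    multiplex: pd.DataFrame  # interlayer metric profiles
    h3: pd.DataFrame  # per-density regressions on interlayer metrics
    strength: pd.DataFrame  # t-tests on connectivity strength
    auc: pd.DataFrame  # AUC regressions
    log: dict = field(default_factory=dict)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "h1_permutation": self.h1,
            "efficiency_profiles": self.efficiency,
            "h2_regression": self.h2,
            "multiplex_profiles": self.multiplex,
            "h3_regression": self.h3,
            "strength_ttests": self.strength,
            "auc_regression": self.auc,
        }

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, table in self.tables().items():
            table.to_csv(directory / f"{name}.csv", index=False)
        (directory / "run_log.json").write_text(json.dumps(self.log, indent=2))


def _multiplex_table(sc_conns, fc_conns, grid: DensityGrid) -> pd.DataFrame:
    """Per-subject, per-hemisphere interlayer metrics across the grid."""
    frames = []
    for sid in sc_conns:
        for scope in ("L", "R"):
            sc_w = hemisphere_subnetwork(sc_conns[sid], scope)
            fc_w = hemisphere_subnetwork(fc_conns[sid], scope)
            pairs = {
                d: MultiplexPair(
                    sc=proportional_threshold(sc_w, d),
                    fc=proportional_threshold(fc_w, d),
                    subject_id=sid,
                )
                for d in grid
            }
            tab = multiplex_profiles(pairs, subject_id=sid)
            tab["hemisphere"] = scope
            frames.append(tab)
    out = pd.concat(frames, ignore_index=True)
    out["modality"] = "SCFC"
    return out


def run_pipeline(
    config: PipelineConfig,
    cohort: Cohort | None = None,
    out_dir: str | Path | None = None,
) -> PipelineReport:
    """Run the full workflow on a (generated or provided) cohort."""
    if cohort is None:
        cohort = generate_cohort(config.sim)
    grid = config.grid()
    chash = config.config_hash()
    log: dict = {
        "config_hash": chash,
        "seed": config.seed,
        "thresholding_modes": {"h1": "consistency", "h2": "proportional",
                               "h3": "proportional"},
        "sigma_repaired": cohort.log.get("sigma_repaired", []),
    }

    sc_conns, fc_conns = build_cohort_connectomes(cohort)
    ft_ids = cohort.subject_ids("FT")
    pt_ids = cohort.subject_ids("PT")

    # --- H1: group edge-overlap permutation tests (consistency networks)
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(2)]
    h1_frames = []
    for conns, mod_seed in zip((sc_conns, fc_conns), seeds):
        cohort_ft = [conns[s] for s in ft_ids]
        cohort_pt = [conns[s] for s in pt_ids]
        table, _ = permutation_profile(
            cohort_ft, cohort_pt, grid, n_perm=config.n_perm, seed=mod_seed,
            degeneracy_min_unique=config.degeneracy_min_unique,
        )
        h1_frames.append(table)
    h1 = pd.concat(h1_frames, ignore_index=True)
    log["h1_flagged_densities"] = {
        mod: sorted(h1.loc[(h1.modality == mod) & h1.flagged, "density"].tolist())
        for mod in h1["modality"].unique()
    }

    # --- H2: efficiency profiles (proportional networks) + regression
    efficiency = efficiency_profiles({**sc_conns}, grid)
    efficiency = pd.concat(
        [efficiency, efficiency_profiles({**fc_conns}, grid)], ignore_index=True
    )
    subjects = cohort.metadata_frame()
    h2 = fit_density_models(efficiency, subjects, max_density=config.max_density)

    # --- H3: interlayer metrics + regression
    multiplex = _multiplex_table(sc_conns, fc_conns, grid)
    h3_profiles = multiplex.rename(columns={"metric": "metric"}).copy()
    h3_profiles.loc[~h3_profiles["defined"], "value"] = np.nan
    h3 = fit_density_models(
        h3_profiles[
            ["subject_id", "modality", "metric", "hemisphere", "density", "value"]
        ],
        subjects,
        max_density=config.max_density,
    )

    # --- exploratory: strength t-tests and AUC regressions
    strength_rows = []
    for mod, conns in (("SC", sc_conns), ("FC", fc_conns)):
        ft_scores = [
            strength_score(conns[s], neg_policy=config.neg_policy) for s in ft_ids
        ]
        pt_scores = [
            strength_score(conns[s], neg_policy=config.neg_policy) for s in pt_ids
        ]
        t, df, p = strength_ttest(ft_scores, pt_scores)
        strength_rows.append(
            {
                "modality": mod,
                "mean_ft": float(np.mean(ft_scores)),
                "mean_pt": float(np.mean(pt_scores)),
                "t": t,
                "df": df,
                "p": p,
                "n_ft": len(ft_scores),
                "n_pt": len(pt_scores),
            }
        )
    strength = pd.DataFrame(strength_rows)
    auc = fit_auc_models(efficiency, subjects, grid)

    log["excluded_regression_densities"] = [
        float(d) for d in grid if d > config.max_density + 1e-9
    ]
    report = PipelineReport(
        config=config,
        h1=h1,
        efficiency=efficiency,
        h2=h2,
        multiplex=multiplex,
        h3=h3,
        strength=strength,
        auc=auc,
        log=log,
    )
    for table in report.tables().values():
        table["config_hash"] = chash
        table["run_seed"] = config.seed
    if out_dir is not None:
        report.write(out_dir)
    return report


def render_summary(report: PipelineReport, alpha: float | None = None) -> str:
    """Human-readable per-density significance summary (stars after BH)."""
    alpha = alpha if alpha is not None else report.config.alpha
    lines = [
        f"neomux run {report.log.get('config_hash', '?')} "
        f"(seed {report.log.get('seed', '?')})",
        "",
        "H1: group edge-overlap permutation tests",
    ]
    for _, row in report.h1.iterrows():
        if row["flagged"]:
            status = "excluded (degenerate null)"
        elif pd.notna(row["p_adjusted"]) and row["p_adjusted"] < alpha:
            status = f"p_adj={row['p_adjusted']:.4f} *"
        else:
            padj = row["p_adjusted"]
            status = f"p_adj={padj:.4f}" if pd.notna(padj) else "p_adj=NA"
        lines.append(
            f"  {row['modality']} d={row['density']:.2f} "
            f"overlap={row['empirical_overlap']:.3f} {status}"
        )
    lines.append("")
    lines.append("Exploratory: connectivity strength (Welch t-test)")
    for _, row in report.strength.iterrows():
        star = " *" if row["p"] < alpha else ""
        lines.append(
            f"  {row['modality']}: FT={row['mean_ft']:.4f} PT={row['mean_pt']:.4f} "
            f"t={row['t']:.2f} p={row['p']:.4f}{star}"
        )
    for name, table in (("H2", report.h2), ("H3", report.h3)):
        sig = table[(table["term"] != "Intercept") & (table["p_adjusted"] < alpha)]
        lines.append("")
        lines.append(f"{name}: {len(sig)} significant term(s) after BH")
        for _, row in sig.iterrows():
            lines.append(
                f"  {row['metric']} {row['modality']} d={row['density']} "
                f"{row['term']}: est={row['estimate']:.4g} "
                f"p_adj={row['p_adjusted']:.4f} *"
            )
    return "\n".join(lines)
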
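"""End-to-end orchestration: features -> MSN -> gradients -> dispersions ->
trajectories -> mediation -> molecular association.

``run_pipeline`` executes every stage on files in the canonical delimited
formats and writes tidy result tables, a JSON run manifest (parameters,
seeds, versions) and a log. All randomness is derived from the single
config seed, so reruns with the same config are bit-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .msn import MSNMatrix, build_msn
from .manifold import embed_msn, build_template, align_gradients
from .dispersion import dispersion_table
from .harmonize import combat_fit_transform
from .trajectories import SplineTrajectory, fit_trajectory, effect_size, fdr_correct
from .mediation import multiple_mediation
from .molecular import spin_permutations, pls1, pls_significance, bootstrap_gene_z, receptor_regression
from . import io as mio

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("msngrad")


@dataclass
class PipelineConfig:
    features_path: str
    metadata_path: str
    partition_path: str
    out_dir: str
    gene_matrix_path: str = None
    receptor_matrix_path: str = None
    behavior_columns: list = field(default_factory=list)
    # manifold
    density: float = 0.10
    alpha: float = 0.5
    diffusion_time: float = 0.0
    n_components: int = 3
    # harmonization
    harmonize_edges: bool = True
    harmonize_dispersions: bool = True
    # trajectories
    n_basis: int = 10
    gaic_k: float = 3.0
    grid_size: int = 100
    window_alpha: float = 0.05
    # inference
    n_boot: int = 1000
    n_perm: int = 1000
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path):
        import yaml

        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _covariates(meta_df, subject_ids):
    m = meta_df.loc[subject_ids]
    sex01 = (m["sex"].astype(str) == "M").astype(float).to_numpy()
    return np.column_stack([sex01, m["etiv"].to_numpy(dtype=float)])


def run_pipeline(config: PipelineConfig) -> dict:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO))
    fh = logging.FileHandler(out / "pipeline.log", mode="w")
    log.addHandler(fh)
    results = {}
    state = {"stage": "init"}

    def _stage(name):
        state["stage"] = name
        log.info("stage: %s", name)

    try:
        _stage("load")
        cohort, meta = mio.load_cohort(config.features_path, config.metadata_path)
        partition = mio.load_partition(config.partition_path)
        subject_ids = [s.subject_id for s in cohort]
        ages = np.array([s.age for s in cohort])
        sites = np.array([s.site for s in cohort])
        cov = _covariates(meta, subject_ids)
        cov_full = np.column_stack([ages, cov])
        R = cohort[0].X.shape[0]
        iu = np.triu_indices(R, k=1)

        _stage("msn")
        msns = [build_msn(s.X) for s in cohort]

        if config.harmonize_edges and len(np.unique(sites)) > 1:
            _stage("harmonize-edges")
            edges = np.stack([m.values[iu] for m in msns])
            keep = edges.std(axis=0) > 0
            edges_h = edges.copy()
            edges_h[:, keep], _ = combat_fit_transform(
                edges[:, keep], sites, cov_full
            )
            new = []
            for i, m in enumerate(msns):
                V = np.eye(R)
                V[iu] = edges_h[i]
                V = V + V.T - np.eye(R)
                new.append(MSNMatrix(V, list(m.region_ids)))
            msns = new

        _stage("template")
        template = build_template(
            msns, n_components=config.n_components, density=config.density,
            alpha=config.alpha, t=config.diffusion_time,
        )
        mio.save_gradients(template, out / "template_gradients.csv",
                           out / "template_gradients.json")

        _stage("embed-align")
        aligned = []
        for m in msns:
            gs = embed_msn(
                m, n_components=config.n_components, density=config.density,
                alpha=config.alpha, t=config.diffusion_time,
            )
            aligned.append(align_gradients(gs, template))

        _stage("dispersion")
        tables = [dispersion_table(g, partition) for g in aligned]
        names = partition.names
        K = len(names)
        measure_names = (
            ["global", "within_total"]
            + [f"within_{n}" for n in names]
            + [f"between_{names[i]}_{names[j]}" for i in range(K) for j in range(i + 1, K)]
        )
        M = np.column_stack(
            [np.array([t.global_dispersion for t in tables])]
            + [np.array([t.within.sum() for t in tables])]
            + [np.array([t.within[k] for t in tables]) for k in range(K)]
            + [np.array([t.between[i, j] for t in tables])
               for i in range(K) for j in range(i + 1, K)]
        )
        ecc = np.stack([t.eccentricity for t in tables])   # subjects x regions

        tidy = []
        for si, sid in enumerate(subject_ids):
            for mi, mn in enumerate(measure_names):
                tidy.append((sid, mn, M[si, mi]))
        pd.DataFrame(tidy, columns=["subject_id", "measure", "value"]).to_csv(
            out / "dispersions.csv", index=False
        )

        if config.harmonize_dispersions and len(np.unique(sites)) > 1:
            _stage("harmonize-dispersions")
            M, _ = combat_fit_transform(M, sites, cov_full)
            keep = ecc.std(axis=0) > 0
            ecc_h = ecc.copy()
            ecc_h[:, keep], _ = combat_fit_transform(ecc[:, keep], sites, cov_full)
            ecc = ecc_h

        _stage("trajectories")
        rows = []
        for mi, mn in enumerate(measure_names):
            fit = fit_trajectory(
                ages, M[:, mi], cov, n_basis=config.n_basis, gaic_k=config.gaic_k,
                grid_size=config.grid_size, alpha=config.window_alpha,
                seed=config.seed + 1000 + mi,
            )
            rows.append(
                {
                    "measure": mn, "signed_r2": fit.signed_r2, "r2": fit.pseudo_r2,
                    "p": fit.p_value, "edf": fit.edf,
                    "windows": json.dumps(fit.windows),
                }
            )
        traj = pd.DataFrame(rows)
        traj["p_fdr"], traj["significant"] = fdr_correct(traj["p"].to_numpy())
        traj.to_csv(out / "trajectories.csv", index=False)
        results["trajectories"] = traj

        _stage("regional-effects")
        regional = np.zeros(R)
        est = SplineTrajectory(n_basis=config.n_basis, gaic_k=config.gaic_k,
                               grid_size=config.grid_size)
        for r in range(R):
            if ecc[:, r].std() == 0:
                continue
            est.fit(ages, ecc[:, r], cov)
            regional[r] = effect_size(est.fit_)
        pd.DataFrame(
            {"region": mio.region_names(R), "signed_r2": regional}
        ).to_csv(out / "regional_effects.csv", index=False)
        results["regional_effects"] = regional

        behaviors = [c for c in config.behavior_columns if c in meta.columns]
        if behaviors:
            _stage("mediation")
            med_rows = []
            mediators = M[:, 2 : 2 + K]   # within-network dispersions
            for bc in behaviors:
                y = meta.loc[subject_ids, bc].to_numpy(dtype=float)
                res = multiple_mediation(
                    ages, mediators, y, covariates=cov,
                    n_boot=config.n_boot, seed=config.seed + 2000,
                )
                for j, nm in enumerate(names):
                    lo, hi = res.ci[f"indirect_{j}"]
                    med_rows.append(
                        {
                            "behavior": bc, "mediator": f"within_{nm}",
                            "a": res.a[j], "b": res.b[j],
                            "indirect": res.indirect[j], "ci_lo": lo, "ci_hi": hi,
                            "p": res.p[f"indirect_{j}"], "p_fdr": res.p_fdr[j],
                        }
                    )
                lo, hi = res.ci["indirect_joint"]
                med_rows.append(
                    {
                        "behavior": bc, "mediator": "joint",
                        "a": np.nan, "b": np.nan, "indirect": res.indirect_joint,
                        "ci_lo": lo, "ci_hi": hi, "p": res.p["indirect_joint"],
                        "p_fdr": np.nan,
                    }
                )
                med_rows[-1]["proportion_mediated"] = res.proportion_mediated
            med = pd.DataFrame(med_rows)
            med.to_csv(out / "mediation.csv", index=False)
            results["mediation"] = med

        if (config.gene_matrix_path or config.receptor_matrix_path) and partition.coords is not None:
            _stage("molecular")
            nulls = spin_permutations(
                partition.coords, n_perm=config.n_perm, seed=config.seed + 3000
            )
            if config.gene_matrix_path:
                genes, _, gene_ids = mio.load_matrix(config.gene_matrix_path)
                res = bootstrap_gene_z(
                    genes, regional, n_boot=config.n_boot,
                    top_k=min(1000, genes.shape[1]), seed=config.seed + 3100,
                )
                res.p_perm = pls_significance(genes, regional, nulls)
                df = pd.DataFrame(
                    {
                        "gene": [gene_ids[i] for i in res.ranked_genes],
                        "weight": res.weights[res.ranked_genes],
                        "z": res.gene_z[res.ranked_genes],
                        "p": res.gene_p[res.ranked_genes],
                        "p_fdr": res.gene_p_fdr[res.ranked_genes],
                    }
                )
                df.to_csv(out / "pls_genes.csv", index=False)
                results["pls"] = res
            if config.receptor_matrix_path:
                rec, _, rec_ids = mio.load_matrix(config.receptor_matrix_path)
                model = receptor_regression(
                    rec, regional, nulls, n_boot=config.n_boot,
                    seed=config.seed + 3200,
                )
                df = pd.DataFrame(
                    {
                        "receptor": rec_ids, "beta": model.coefficients,
                        "lmg_share": model.lmg_shares,
                        "ci_lo": model.share_cis[:, 0], "ci_hi": model.share_cis[:, 1],
                        "p_spin": model.p_spin, "p_spin_fdr": model.p_spin_fdr,
                    }
                )
                df.to_csv(out / "receptors.csv", index=False)
                results["receptors"] = model

        manifest = {"version": __version__, "config": asdict(config)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        _stage("done")
        return results
    except Exception as exc:
        log.error("pipeline aborted at stage %s: %s", state["stage"], exc)
        raise RuntimeError(f"pipeline stage '{state['stage']}' failed: {exc}") from exc
    finally:
        log.removeHandler(fh)
        fh.close()
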
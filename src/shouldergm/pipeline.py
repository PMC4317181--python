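"""Config-driven orchestration of the full analysis chain.

load -> mirror left elements -> (optionally) slide semilandmarks -> GPA +
tangent projection -> between-group PCA with fossil projection and 95%
ellipses -> Procrustes-distance affinity (MST, Ward dendrogram, nearest
extant group per fossil) -> shape ~ centroid-size regression with
permutation test and size-shape PCA of its residuals -> shape ~ torsion
regression -> torsion summary table.  Humerus and glenoid subsets are
analysed independently; a run is fully determined by its config and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .affinity import AffinityResult, affinity_analysis
from .allometry_regression import (
    RegressionResult,
    permutation_pvalue,
    shape_regression,
    torsion_summary_table,
)
from .landmark_io import (
    LandmarkDataset,
    load_protocol,
    mirror_left_specimens,
    read_landmarks,
    validate_against_protocol,
)
from .ordination import BgPCAResult, PCAResult, bgpca, group_score_ellipses, size_shape_pca
from .sliding_semilandmarks import SlideResult, slide_dataset
from .superimposition import AlignedDataset, gpa

logger = logging.getLogger("shouldergm")

__all__ = ["RunConfig", "RunReport", "run_analysis", "run_analysis_on_dataset"]


@dataclass
class RunConfig:
    """One analysis run: dataset, protocol, policies, seed, output paths."""

    data_path: str | Path
    protocol: str = "humerus"  # bundled name or YAML path
    data_format: str | None = None
    slide: str = "default"  # default | all | none
    torsion_covariate: str = "torsion_deg"
    n_permutations: int = 10_000
    seed: int = 0
    output_dir: str | Path | None = None
    mirror_left: bool = True
    gpa_tol: float = 1e-10
    slide_tol: float = 1e-8
    ellipse_level: float = 0.95


@dataclass
class RunReport:
    """All numeric outputs of one run plus the reproducibility manifest."""

    dataset: LandmarkDataset
    aligned: AlignedDataset
    slide: SlideResult | None
    bgpca: BgPCAResult
    ellipses: dict[str, object]
    affinity: AffinityResult
    cs_regression: RegressionResult
    size_shape: PCAResult
    torsion_regression: RegressionResult | None
    torsion_table: pd.DataFrame | None
    manifest: dict = field(default_factory=dict)

    def variance_table(self) -> pd.DataFrame:
        """Per-component variance table (variance, % total, % cumulative)."""
        return pd.DataFrame(
            {
                "component": [f"PC{i + 1}" for i in range(self.bgpca.n_components)],
                "variance": self.bgpca.eigenvalues,
                "pct_total_variance": self.bgpca.pct_variance,
                "pct_cumulative": self.bgpca.cumulative_pct,
            }
        )

    def distance_table(self) -> pd.DataFrame:
        aff = self.affinity
        return pd.DataFrame(
            aff.distance_matrix, index=aff.labels, columns=aff.labels
        )

    def scores_table(self) -> pd.DataFrame:
        rows = []
        for sid, sc in {**self.bgpca.scores, **self.bgpca.projected_scores}.items():
            row = {"specimen_id": sid, "group": self.bgpca.specimen_groups[sid]}
            row.update({f"PC{i + 1}": v for i, v in enumerate(sc)})
            rows.append(row)
        return pd.DataFrame(rows)


def _resolve_slide(policy: str, dataset: LandmarkDataset) -> bool:
    if policy == "all":
        return True
    if policy == "none":
        return False
    if policy == "default":
        return dataset.protocol.slide_by_default and bool(dataset.protocol.curves)
    raise ValueError(f"unknown slide policy {policy!r} (expected default/all/none)")


def run_analysis_on_dataset(dataset: LandmarkDataset, config: RunConfig) -> RunReport:
    """Run the full stage graph on an in-memory dataset."""
    if config.mirror_left:
        dataset = mirror_left_specimens(dataset)
    issues = validate_against_protocol(dataset)
    if issues:
        raise ValueError(f"dataset failed validation: {issues[:3]}")

    slide_result: SlideResult | None = None
    if _resolve_slide(config.slide, dataset):
        logger.info("sliding semilandmarks (%d curves)", len(dataset.protocol.curves))
        slide_result = slide_dataset(dataset, tol=config.slide_tol, gpa_tol=config.gpa_tol)
        dataset = slide_result.dataset
        aligned = slide_result.aligned
    else:
        aligned = gpa(dataset, tol=config.gpa_tol)
    logger.info(
        "GPA: %d iterations, converged=%s", aligned.iterations, aligned.converged
    )

    bg = bgpca(aligned)
    ellipses = group_score_ellipses(bg, level=config.ellipse_level)
    aff = affinity_analysis(aligned)

    cs_reg = shape_regression(aligned, "centroid_size")
    permutation_pvalue(cs_reg, n_perm=config.n_permutations, seed=config.seed)
    ssp = size_shape_pca(cs_reg.residuals)

    torsion_reg = None
    torsion_tab = None
    with_torsion = [
        s for s in dataset.specimens if config.torsion_covariate in s.covariates
    ]
    extant_with_torsion = [s for s in with_torsion if not s.is_fossil]
    if len(extant_with_torsion) >= 3:
        torsion_reg = shape_regression(aligned, config.torsion_covariate)
        permutation_pvalue(torsion_reg, n_perm=config.n_permutations, seed=config.seed + 1)
        by_group: dict[str, list[float]] = {}
        for s in extant_with_torsion:
            by_group.setdefault(s.group, []).append(s.covariates[config.torsion_covariate])
        fossil_vals = {
            s.specimen_id: s.covariates[config.torsion_covariate]
            for s in with_torsion
            if s.is_fossil
        }
        torsion_tab = torsion_summary_table(by_group, fossil_vals)
    else:
        logger.warning(
            "covariate %r missing for extant specimens; torsion stage skipped",
            config.torsion_covariate,
        )

    from . import __version__ as pkg_version

    manifest = {
        "version": pkg_version,
        "seed": config.seed,
        "n_specimens": len(dataset),
        "n_extant": len(dataset.extant),
        "n_fossils": len(dataset.fossils),
        "protocol": dataset.protocol.name,
        "k": dataset.protocol.expected_k,
        "slide_policy": config.slide,
        "slid": slide_result is not None,
        "slide_iterations": slide_result.n_outer_iterations if slide_result else 0,
        "slide_objective_trace": slide_result.objective_trace if slide_result else [],
        "gpa_iterations": aligned.iterations,
        "gpa_converged": bool(aligned.converged),
        "gpa_tol": config.gpa_tol,
        "n_permutations": config.n_permutations,
    }
    return RunReport(
        dataset=dataset,
        aligned=aligned,
        slide=slide_result,
        bgpca=bg,
        ellipses=ellipses,
        affinity=aff,
        cs_regression=cs_reg,
        size_shape=ssp,
        torsion_regression=torsion_reg,
        torsion_table=torsion_tab,
        manifest=manifest,
    )


def run_analysis(config: RunConfig) -> RunReport:
    """Load the configured dataset, run all stages, optionally write reports."""
    protocol = load_protocol(config.protocol)
    dataset = read_landmarks(
        config.data_path, protocol, fmt=config.data_format, mirror_left=False
    )
    report = run_analysis_on_dataset(dataset, config)
    if config.output_dir is not None:
        write_report(report, config.output_dir)
    return report


def write_report(report: RunReport, output_dir: str | Path) -> None:
    """Write CSV tables, newick, MST edge list, figures and the JSON manifest."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    float_fmt = "%.10g"
    report.variance_table().to_csv(out / "variance_table.csv", index=False, float_format=float_fmt)
    report.distance_table().to_csv(out / "procrustes_distances.csv", float_format=float_fmt)
    report.scores_table().to_csv(out / "bgpca_scores.csv", index=False, float_format=float_fmt)
    pd.DataFrame(
        report.affinity.mst_edges, columns=["from", "to", "distance"]
    ).to_csv(out / "mst_edges.csv", index=False, float_format=float_fmt)
    (out / "ward_dendrogram.nwk").write_text(report.affinity.dendrogram.newick() + "\n")
    reg_rows = [_regression_row(report.cs_regression)]
    if report.torsion_regression is not None:
        reg_rows.append(_regression_row(report.torsion_regression))
    pd.DataFrame(reg_rows).to_csv(out / "regressions.csv", index=False, float_format=float_fmt)
    if report.torsion_table is not None:
        report.torsion_table.to_csv(out / "torsion_summary.csv", index=False, float_format=float_fmt)
    nearest = {f: labs for f, labs in report.affinity.nearest_extant.items()}
    manifest = dict(report.manifest)
    manifest["nearest_extant"] = nearest
    manifest["ellipses"] = {
        g: {
            "center": e.center.tolist(),
            "semi_axes": e.semi_axes.tolist(),
            "orientation": e.orientation,
            "level": e.level,
        }
        for g, e in report.ellipses.items()
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    try:
        _plot_bgpca(report, out / "bgpca_scatter.png")
    except Exception as exc:  # plotting must never kill an analysis run
        logger.warning("could not render scatter figure: %s", exc)


def _regression_row(reg: RegressionResult) -> dict:
    return {
        "covariate": reg.covariate_name,
        "pct_variance_explained": reg.pct_variance_explained,
        "permutation_p": reg.permutation_p,
        "n_permutations": reg.n_permutations,
        "n_fit": len(reg.fit_ids),
    }


def _plot_bgpca(report: RunReport, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Ellipse

    fig, ax = plt.subplots(figsize=(7, 6))
    bg = report.bgpca
    groups = sorted({g for g in bg.specimen_groups.values() if not g.startswith("fossil:")})
    cmap = plt.get_cmap("tab10")
    for gi, g in enumerate(groups):
        pts = np.array(
            [sc[:2] for sid, sc in bg.scores.items() if bg.specimen_groups[sid] == g]
        )
        ax.scatter(pts[:, 0], pts[:, 1], s=14, color=cmap(gi % 10), label=g)
        if g in report.ellipses:
            e = report.ellipses[g]
            ax.add_patch(
                Ellipse(
                    e.center,
                    2 * e.semi_axes[0],
                    2 * e.semi_axes[1],
                    angle=np.degrees(e.orientation),
                    fill=False,
                    color=cmap(gi % 10),
                )
            )
    for sid, sc in bg.projected_scores.items():
        ax.scatter([sc[0]], [sc[1]], marker="*", s=120, color="black")
        ax.annotate(sid, (sc[0], sc[1]), fontsize=7)
    pv = bg.pct_variance
    ax.set_xlabel(f"bgPC1 ({pv[0]:.2f}%)")
    if len(pv) > 1:
        ax.set_ylabel(f"bgPC2 ({pv[1]:.2f}%)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
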
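"""End-to-end orchestration: simulate -> f4 -> qpAdm -> dating -> calibrate
-> propagate -> sensitivity, driven by a YAML/dict config.

Every numeric output is written with a meta block (package version, root
seed, config hash) so a run is reproducible from its artefacts alone.  All
randomness flows from the single root seed through named per-stage
substreams.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .io import read_eigenstrat, read_population_table
from .fstats import BlockPartition, sex_bias_z, symmetry_scan
from .qpadm import QpAdm, pca_fit_project
from .dating import AdmixtureDecay, plot_decay
from .radiocarbon import (
    DietSpec,
    ReservoirSpec,
    apply_reservoir,
    calibrate,
    mix_curves,
    read_curve_14c,
    sensitivity_grid,
)
from .chronology import (
    AnchorDate,
    GenerationInterval,
    chronology_sensitivity,
    propagate_gaussian,
    propagate_monte_carlo,
    threshold_test,
)
from .simulate import SimConfig, simulate_cohort, simulate_toy_calibration_curve

log = logging.getLogger("admixchron")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def _stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed below 2^31."""
    h = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def validate_config(cfg: dict) -> None:
    """Fail before any compute on obviously broken configs."""
    if "seed" not in cfg:
        raise PipelineError("config validation: missing 'seed'")
    if "simulate" not in cfg and "paths" not in cfg:
        raise PipelineError(
            "config validation: need either a 'simulate' block or 'paths' "
            "to genotype data"
        )
    cal = cfg.get("calibration", {})
    curves = cal.get("curves")
    if curves is not None:
        for role in ("terrestrial", "marine"):
            p = curves.get(role)
            if p is None or not Path(p).exists():
                raise PipelineError(
                    f"config validation: calibration curve path for "
                    f"{role!r} missing or not found: {p}"
                )


def _write_json(path: Path, payload: dict, meta: dict) -> None:
    path.write_text(json.dumps({"meta": meta, **payload}, indent=2, default=str))


def _write_tsv(path: Path, df: pd.DataFrame, meta: dict) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {json.dumps(meta, default=str)}\n")
    df.to_csv(path, sep="\t", index=False, mode="a")


def demo_config(outdir: str | Path = "demo_out", seed: int = 7) -> dict:
    """A self-contained configuration exercising every stage on synthetic data."""
    return {
        "seed": seed,
        "output_dir": str(outdir),
        "simulate": {
            "n_snps_per_chrom": 800,
            "n_chroms": 22,
            "n_admixed": 20,
            "alpha_autosome": 0.40,
            "alpha_X": 0.30,
            "admixture_generations": 30.0,
            "missing_rate": 0.05,
        },
        "fstats": {
            "targets": ["Admixed"],
            "baseline": "EastAsian",
            "popC": "Papuan",
            "popD": "Outgroup0",
            "block_size": 0.05,
        },
        "qpadm": {
            "target": "Admixed",
            "sources": ["EastAsian", "Papuan"],
            "rights": ["Outgroup0", "OutEastAsian", "OutPapuan", "Outgroup1"],
            "sex_bias": True,
        },
        "dating": {
            "source1": "EastAsian",
            "source2": "Papuan",
            "binsize": 0.001,
            "mindis": 0.005,
            "maxdis": 0.5,
        },
        "calibration": {
            "measurement": [2800.0, 20.0],
            "toy_curves": {"slope": 1.0, "reservoir_offset": 500.0},
            "delta_R": [-140.0, 35.0],
            "marine_fraction": [0.5, 0.1],
        },
        "chronology": {
            "generation_interval": [28.4, 0.7],
            "threshold": 3200.0,
            "n_draws": 200000,
            "sensitivity": {
                "delta_R": [[-250.0, 50.0], [-140.0, 35.0], [0.0, 0.0]],
                "marine_fraction": [0.0, 0.25, 0.5, 1.0],
            },
        },
    }


def run_pipeline(config: dict | str | Path) -> dict:
    """Execute the configured stages; returns a report bundle of results/paths."""
    if not isinstance(config, dict):
        config = load_config(config)
    validate_config(config)
    seed = int(config["seed"])
    outdir = Path(config.get("output_dir", "admixchron_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {
        "package_version": __version__,
        "seed": seed,
        # hash the scientific config only, not where it writes
        "config_sha256": hashlib.sha256(
            json.dumps(
                {k: v for k, v in config.items() if k != "output_dir"},
                sort_keys=True, default=str,
            ).encode()
        ).hexdigest()[:16],
    }
    bundle: dict = {"meta": meta, "output_dir": str(outdir)}
    report_lines = [
        "# admixchron pipeline report",
        f"version {__version__}, seed {seed}, config {meta['config_sha256']}",
        "",
    ]

    def stage(name):
        def wrap(fn):
            t0 = time.time()
            try:
                out = fn()
            except Exception as err:
                raise PipelineError(f"stage {name!r} failed: {err}") from err
            log.info("stage %-12s done in %.2fs", name, time.time() - t0)
            return out

        return wrap

    # ---------------- data ----------------
    truth = None
    if "simulate" in config:
        def _sim():
            sim = SimConfig(**config["simulate"], seed=_stage_seed(seed, "simulate"))
            return simulate_cohort(sim)

        ds, truth = stage("simulate")(_sim)
        report_lines.append(
            f"Simulated cohort: {ds.n_variants} SNPs x {ds.n_samples} samples "
            f"(alpha={truth['alpha_autosome']}, n={truth['admixture_generations']})"
        )
    else:
        def _load():
            d = read_eigenstrat(config["paths"]["genotypes"])
            popfile = config["paths"].get("populations")
            if popfile:
                mapping = read_population_table(popfile)
                d.samples["population"] = [
                    mapping.get(s, p)
                    for s, p in zip(d.samples["id"], d.samples["population"])
                ]
            return d

        ds = stage("load")(_load)
        report_lines.append(
            f"Loaded {ds.n_variants} SNPs x {ds.n_samples} samples"
        )

    autosomal = ds.restrict(chromosome_class="autosomes")

    # ---------------- f4 symmetry scan ----------------
    if "fstats" in config:
        fcfg = config["fstats"]

        def _f4():
            blocks = BlockPartition.contiguous(
                autosomal, fcfg.get("block_size", 0.05)
            )
            return symmetry_scan(
                autosomal, fcfg["targets"], fcfg["baseline"],
                fcfg["popC"], fcfg["popD"], blocks=blocks,
            )

        f4_df = stage("fstats")(_f4)
        _write_tsv(outdir / "f4_symmetry.tsv", f4_df, meta)
        bundle["f4"] = f4_df
        report_lines += ["", "## f4 symmetry scan", f4_df.to_string(index=False)]

    # ---------------- qpAdm ----------------
    qp_res = qp_res_x = None
    if "qpadm" in config:
        qcfg = config["qpadm"]

        def _qp():
            rights = list(qcfg["rights"])
            return QpAdm(autosomal, qcfg["target"], qcfg["sources"], rights).fit()

        qp_res = stage("qpadm")(_qp)
        bundle["qpadm"] = qp_res
        _write_tsv(outdir / "qpadm.tsv", qp_res.to_frame(), meta)
        report_lines += ["", "## qpAdm", qp_res.summary()]
        if qcfg.get("sex_bias") and (ds.variants["chrom"] == "X").any():
            def _qpx():
                x_ds = ds.restrict(chromosome_class="X")
                blocks = BlockPartition.contiguous(x_ds, 0.05)
                return QpAdm(
                    x_ds, qcfg["target"], qcfg["sources"], qcfg["rights"],
                    blocks=blocks,
                ).fit()

            qp_res_x = stage("qpadm_X")(_qpx)
            z = sex_bias_z(qp_res, qp_res_x, source=qcfg["sources"][-1])
            bundle["sex_bias_z"] = z
            report_lines.append(
                f"sex-bias Z (autosome vs X, {qcfg['sources'][-1]}): {z:.2f}"
            )

    # ---------------- PCA overview figure ----------------
    if "qpadm" in config:
        def _pca():
            refs = config["qpadm"]["sources"]
            return pca_fit_project(autosomal, refs)

        try:
            proj = stage("pca")(_pca)
            bundle["pca"] = proj
            _plot_pca(proj, outdir / "pca.png")
        except Exception as err:  # PCA is an overview, not a headline number
            log.warning("PCA overview skipped: %s", err)

    # ---------------- dating ----------------
    decay = None
    if "dating" in config:
        dcfg = config["dating"]

        def _dates():
            targets = dcfg.get("target_samples")
            if targets is None:
                pop = dcfg.get("target_population", "Admixed")
                targets = list(
                    autosomal.samples.loc[
                        autosomal.samples["population"] == pop, "id"
                    ]
                )
            model = AdmixtureDecay(
                autosomal, targets, dcfg["source1"], dcfg["source2"],
                binsize=dcfg.get("binsize", 0.001),
                maxdis=dcfg.get("maxdis", 1.0),
                alpha=dcfg.get("alpha"),
            )
            return model.fit(mindis=dcfg.get("mindis", 0.005))

        decay = stage("dating")(_dates)
        bundle["dating"] = decay
        _write_tsv(outdir / "decay_curve.tsv", decay.curve.to_frame(), meta)
        decay.to_json(outdir / "decay_fit.json")
        report_lines += ["", "## Admixture dating", decay.summary()]
        ax = plot_decay(decay)
        ax.figure.savefig(outdir / "decay_curve.png", dpi=120)
        import matplotlib.pyplot as plt

        plt.close(ax.figure)

    # ---------------- calibration ----------------
    anchor = None
    cal_grid_df = None
    if "calibration" in config:
        ccfg = config["calibration"]

        def _cal():
            if "curves" in ccfg:
                terr = read_curve_14c(ccfg["curves"]["terrestrial"])
                marine = read_curve_14c(ccfg["curves"]["marine"])
            else:
                toy = ccfg.get("toy_curves", {})
                terr, marine = simulate_toy_calibration_curve(**toy)
            age, sig = ccfg["measurement"]
            rs = ReservoirSpec(*ccfg.get("delta_R", (-140.0, 35.0)))
            diet = DietSpec(*ccfg.get("marine_fraction", (0.5, 0.1)))
            mixed = mix_curves(terr, apply_reservoir(marine, rs), diet)
            return calibrate(age, sig, mixed), terr, marine

        date, terr, marine = stage("calibrate")(_cal)
        anchor = AnchorDate.from_calibrated(date)
        old, young = date.envelope
        bundle["anchor"] = anchor
        report_lines += [
            "",
            "## Radiocarbon anchor",
            f"calibrated {date.mean:.0f} ± {date.sd:.0f} calBP "
            f"(95.4% HPD {old:.0f}-{young:.0f})",
        ]

        sens = config.get("chronology", {}).get("sensitivity")
        if sens:
            def _sens():
                return sensitivity_grid(
                    tuple(ccfg["measurement"]), terr, marine,
                    sens["delta_R"], sens["marine_fraction"],
                )

            cal_grid_df = stage("sensitivity")(_sens)
            _write_tsv(
                outdir / "calibration_sensitivity.tsv",
                cal_grid_df.drop(columns=["date"]), meta,
            )

    # ---------------- chronology ----------------
    if "chronology" in config and decay is not None and anchor is not None:
        hcfg = config["chronology"]

        def _chron():
            g = GenerationInterval(*hcfg.get("generation_interval", (28.4, 0.7)))
            fit = (decay.n_generations, decay.se_generations)
            gau = propagate_gaussian(fit, g, anchor)
            mc = propagate_monte_carlo(
                fit, g, anchor, n_draws=int(hcfg.get("n_draws", 1_000_000)),
                seed=_stage_seed(seed, "chronology"),
            )
            verdict = threshold_test(mc, hcfg.get("threshold", 3200.0))
            table = None
            if cal_grid_df is not None:
                table = chronology_sensitivity(
                    fit, g, cal_grid_df, hcfg.get("threshold", 3200.0)
                )
            return gau, mc, verdict, table

        gau, mc, verdict, sens_table = stage("chronology")(_chron)
        bundle["chronology"] = {"gaussian": gau, "monte_carlo": mc, "verdict": verdict}
        payload = {
            "n_generations": decay.n_generations,
            "se_generations": decay.se_generations,
            "gaussian": {"point": gau.point, "sd": gau.sd, "ci95": gau.ci95},
            "monte_carlo": {"point": mc.point, "sd": mc.sd, "ci95": mc.ci95,
                            "n_draws": mc.n_draws},
            "threshold": verdict.threshold,
            "predates_threshold": verdict.predates,
            "margin_years": verdict.margin,
        }
        _write_json(outdir / "chronology.json", payload, meta)
        report_lines += [
            "",
            "## Calendar admixture date",
            f"gaussian: {gau.point:.0f} ± {gau.sd:.0f} calBP, "
            f"95% CI {gau.ci95[0]:.0f}-{gau.ci95[1]:.0f}",
            f"monte-carlo: 95% CI {mc.ci95[0]:.0f}-{mc.ci95[1]:.0f} "
            f"({mc.n_draws} draws)",
            f"predates {verdict.threshold:.0f} BP: {verdict.predates} "
            f"(margin {verdict.margin:.0f} yr)",
        ]
        if sens_table is not None:
            bundle["chronology_sensitivity"] = sens_table
            _write_tsv(outdir / "chronology_sensitivity.tsv", sens_table, meta)
            _plot_forest(sens_table, verdict.threshold, outdir / "ci_forest.png")

    # ancestry-vs-date overview (admixture proportion per target group)
    if qp_res is not None and truth is not None:
        _plot_ancestry(qp_res, truth, outdir / "ancestry.png")

    (outdir / "report.md").write_text("\n".join(report_lines) + "\n")
    bundle["report"] = str(outdir / "report.md")
    return bundle


# ----------------------------------------------------------------------
# figures
# ----------------------------------------------------------------------

def _plot_pca(proj, path: Path) -> None:
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for pop, grp in proj.coords.groupby("population"):
        ax.scatter(grp["PC1"], grp["PC2"], s=12, label=pop, alpha=0.7)
    ax.set_xlabel(f"PC1 ({proj.explained_variance[0]:.1%})")
    ax.set_ylabel(f"PC2 ({proj.explained_variance[1]:.1%})")
    ax.legend(frameon=False, fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_ancestry(qp_res, truth, path: Path) -> None:
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    w = qp_res.weight(qp_res.model.sources[-1])
    se = qp_res.weight_se(qp_res.model.sources[-1])
    ax.errorbar([0], [w], yerr=[1.96 * se], fmt="o", capsize=4,
                label="qpAdm estimate (95% CI)")
    ax.axhline(truth["alpha_autosome"], color="grey", ls="--",
               label="simulated truth")
    ax.set_ylabel(f"{qp_res.model.sources[-1]} ancestry fraction")
    ax.set_xticks([0], [qp_res.model.target])
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_forest(sens_table: pd.DataFrame, threshold: float, path: Path) -> None:
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 0.4 * len(sens_table) + 1.2))
    for i, row in sens_table.iterrows():
        ax.plot([row["ci_young"], row["ci_old"]], [i, i], "-",
                color="tab:blue", lw=2)
        ax.plot(row["point"], i, "o", color="tab:blue", ms=4)
    ax.axvline(threshold, color="red", ls="--", lw=1, label=f"{threshold:.0f} BP")
    ax.set_yticks(
        range(len(sens_table)),
        [
            f"dR={r.delta_R:+.0f}, p={r.marine_fraction:.2f}"
            for r in sens_table.itertuples()
        ],
        fontsize=7,
    )
    ax.set_xlabel("admixture date (calBP)")
    ax.invert_xaxis()
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
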
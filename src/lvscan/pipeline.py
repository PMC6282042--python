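"""End-to-end orchestration: simulate/load -> adjust -> SEM -> kinship ->
GBLUP -> window scan -> effect classification.

Every run writes its stage outputs, a config digest and a summary into the
run directory, so a run is reproducible from the directory contents alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as _classify
from . import gblup as _gblup
from . import kinship as _kinship
from . import phenotypes as _phen
from . import sem as _sem
from . import synthetic as _syn
from . import windows as _win
from .datatypes import GenotypeMatrix, PedigreeTable

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "write_bed", "DEFAULT_SEM_MODEL"]

log = logging.getLogger(__name__)

DEFAULT_SEM_MODEL = """\
carcass =~ QG + FOR + MARB
meat =~ JC + TD + CT
meat ~ carcass
"""


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str, kind: str = "runtime"):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.kind = kind  # validation | convergence | io | runtime


@dataclass
class RunConfig:
    outdir: str = "run"
    seed: int = 0
    simulate: dict | None = None  # SimConfig overrides
    inputs: dict | None = None  # paths: pedigree, genotypes, markers, phenotypes
    sem_model: str = DEFAULT_SEM_MODEL
    indicator_traits: tuple[str, ...] = ("QG", "FOR", "MARB", "JC", "TD", "CT")
    growth_traits: tuple[str, ...] = ()
    qc: dict = field(default_factory=lambda: {"maf_min": 0.05, "callrate_min": 0.9})
    blend_alpha: float = 0.95
    window_size: int = 20
    classifier: dict = field(default_factory=dict)
    bootstrap_draws: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise PipelineError("config", f"unknown config keys {sorted(bad)}",
                                "validation")
        for key in ("indicator_traits", "growth_traits"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate(self) -> None:
        if self.simulate is None and self.inputs is None:
            raise PipelineError(
                "config", "either a simulation block or input paths required",
                "validation",
            )
        if self.simulate is not None and self.inputs is not None:
            raise PipelineError(
                "config", "give simulation block or input paths, not both",
                "validation",
            )
        if self.inputs is not None:
            need = {"pedigree", "genotypes", "markers", "phenotypes"}
            missing = need - set(self.inputs)
            if missing:
                raise PipelineError(
                    "config", f"missing input paths: {sorted(missing)}",
                    "validation",
                )
            for k, p in self.inputs.items():
                if not Path(p).exists():
                    raise PipelineError(
                        "config", f"input path {k}={p} does not exist", "io"
                    )

    def digest(self) -> str:
        blob = json.dumps(
            {k: getattr(self, k) for k in self.__dataclass_fields__
             if k != "outdir"},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_or_simulate(cfg: RunConfig):
    if cfg.simulate is not None:
        sim_kwargs = dict(cfg.simulate)
        plan = [
            _syn.QtlSpec(int(w), str(c), float(s))
            for w, c, s in sim_kwargs.pop("qtl_plan", [])
        ]
        sc = _syn.SimConfig(seed=cfg.seed, qtl_plan=plan, **sim_kwargs)
        sim = _syn.simulate_dataset(sc)
        return sim.pedigree, sim.genotypes, sim.indicators, sim
    paths = cfg.inputs
    ped = PedigreeTable.read(paths["pedigree"])
    geno = GenotypeMatrix.read_plink_text(paths["genotypes"], paths["markers"])
    phen = pd.read_csv(paths["phenotypes"], sep="\t")
    return ped, geno, phen, None


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages; returns the summary dict (also written to disk)."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config_digest": cfg.digest(), "seed": cfg.seed}

    def stage(name):
        log.info("stage: %s", name)

    try:
        stage("data")
        ped, geno, phen, sim = _load_or_simulate(cfg)
        summary["n_animals_pedigree"] = ped.n_animals
        summary["n_records"] = len(phen)

        stage("adjust")
        specs = _phen.default_specs(cfg.indicator_traits, tuple(cfg.growth_traits))
        adjusted = _phen.adjust_phenotypes(phen, specs)
        adjusted.to_csv(outdir / "adjusted_phenotypes.tsv", sep="\t", index=False)

        stage("sem")
        model = _sem.SemModel.from_text(cfg.sem_model)
        cols = model.observed
        data = adjusted[cols].dropna()
        S = np.cov(data.to_numpy(float), rowvar=False, ddof=1)
        fit = _sem.fit_ml(S, len(data), model, data=data)
        if not fit.converged:
            raise PipelineError("sem", "ML fit did not converge", "convergence")
        indices = _sem.fit_indices(fit)
        fit.estimates.to_csv(outdir / "sem_estimates.tsv", sep="\t", index=False)
        (outdir / "sem_report.txt").write_text(fit.report() + "\n")
        df_, label = _sem.model_degrees_of_freedom(model)
        gamma = fit.estimates.set_index("name")["value"]
        struct_name = [n for n in gamma.index if n.startswith("gamma[")]
        summary["sem"] = {
            "df": df_,
            "identification": label,
            "chi2": fit.chi2,
            "pvalue": fit.pvalue,
            "structural_coefficients": {n: float(gamma[n]) for n in struct_name},
            "gfi": indices.gfi,
            "agfi": indices.agfi,
            "rmr": indices.rmr,
            "cfi": indices.cfi,
            "rmsea": indices.rmsea,
        }
        if cfg.bootstrap_draws:
            summary["sem"]["bootstrap"] = _sem.bootstrap_model_check(
                data, model, cfg.bootstrap_draws, cfg.seed
            )
        scores = _sem.factor_scores(fit, adjusted[cols].dropna())
        scores.insert(0, "animal", adjusted.loc[scores.index, "animal"].to_numpy())
        scores.to_csv(outdir / "factor_scores.tsv", sep="\t", index=False)

        stage("kinship")
        geno_qc, qc_report = _kinship.snp_qc(geno, **cfg.qc)
        (outdir / "qc_report.json").write_text(
            json.dumps(qc_report.__dict__, indent=2)
        )
        A = _kinship.pedigree_A(ped)
        gids = geno_qc.ids
        A22 = A.submatrix(gids)
        freqs = geno_qc.allele_frequencies()
        G = _kinship.genomic_G(geno_qc, freqs)
        Gb = _kinship.blend_G(G, A22, cfg.blend_alpha)
        Hinv = _kinship.build_H_inverse(
            A.inverse(), A22.inverse(), Gb.inverse(), gids
        )

        stage("gblup")
        lat_x, lat_y = model.latents_x[0], model.latents_y[0]
        rec_ids = scores["animal"].to_numpy()
        yA = scores[lat_x].to_numpy(float)
        yB = scores[lat_y].to_numpy(float)
        ones = np.ones((len(yA), 1))
        X_cond = np.column_stack([ones, yA])
        Zc = geno_qc.dosages - 2.0 * freqs

        vcA = _gblup.estimate_variance_components(yA, ones, Hinv, rec_ids)
        vcB = _gblup.estimate_variance_components(yB, ones, Hinv, rec_ids)
        vcBA = _gblup.estimate_variance_components(yB, X_cond, Hinv, rec_ids)
        rg = _gblup.estimate_genetic_correlation(yA, yB, ones, Hinv, rec_ids)
        summary["variance_components"] = {
            "h2_A": vcA.h2, "h2_A_se": vcA.h2_se,
            "h2_B": vcB.h2, "h2_B_se": vcB.h2_se,
            "r_g": rg["r_g"], "r_g_se": rg["r_g_se"],
            "sigma2_a": {"A": vcA.sigma2_a, "B": vcB.sigma2_a,
                         "B_given_A": vcBA.sigma2_a},
        }

        windows = _win.make_windows(geno_qc.marker_map, cfg.window_size)
        tables = {}
        for tag, y, X, vc in (
            ("carcass", yA, ones, vcA),
            ("meat", yB, ones, vcB),
            ("meat_given_carcass", yB, X_cond, vcBA),
        ):
            sol = _gblup.solve_mme(y, X, Hinv, vc.lam, rec_ids, model_tag=tag)
            u = _gblup.backsolve_snp_effects(sol, Zc, Gb, freqs,
                                             reconstruction_tol=0.2)
            tables[tag] = _win.window_variance(
                u, Zc, windows, vc.sigma2_a, model_tag=tag
            )
        merged = tables["carcass"].copy()
        for tag in ("meat", "meat_given_carcass"):
            merged[f"pct_{tag}"] = tables[tag][f"pct_{tag}"]
        merged.to_csv(outdir / "window_variance.tsv", sep="\t", index=False)

        stage("classify")
        ccfg = _classify.ClassifierConfig(**cfg.classifier)
        calls, counts = _classify.classify_genome(
            tables["carcass"], tables["meat"], tables["meat_given_carcass"], ccfg
        )
        calls.to_csv(outdir / "region_calls.tsv", sep="\t", index=False)
        summary["class_counts"] = counts
        for cls in _classify.CLASSES:
            sub = calls[calls["effect_class"] == cls]
            if cls != "not_associated":
                write_bed(sub, outdir / f"regions_{cls}.bed")
        if sim is not None:
            sim.write(outdir / "simulated_data")
    except PipelineError as err:
        (outdir / "error.json").write_text(
            json.dumps({"stage": err.stage, "kind": err.kind,
                        "message": str(err)}, indent=2)
        )
        raise
    except Exception as err:  # wrap unexpected failures with the stage name
        (outdir / "error.json").write_text(
            json.dumps({"stage": "unknown", "kind": "runtime",
                        "message": str(err)}, indent=2)
        )
        raise

    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


def write_bed(regions: pd.DataFrame, path: str | Path) -> None:
    """Write windows as BED: 0-based half-open, so a window spanning
    1-based-inclusive [start_bp, end_bp] emits (start_bp - 1, end_bp)."""
    if regions["window_id"].duplicated().any():
        raise ValueError("duplicate window ids in BED export")
    rows = regions.sort_values(["chrom", "start_bp"])
    with open(path, "w") as fh:
        fh.write("# chrom\tstart\tend\tname\n")
        for r in rows.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.start_bp - 1}\t{r.end_bp}\t{r.window_id}\n")
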
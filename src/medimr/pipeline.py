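"""End-to-end orchestration of the diet -> metabolite -> stone-risk analysis.

Stages (mirroring the study design):

1. exposure -> outcome MR per exposure file (IVW-MRE primary, plus Egger,
   weighted median, Cochran's Q, and MR-PRESSO sensitivity columns);
2. metabolome-wide MR: each mediator -> outcome;
3. significance screening at the nominal level with the
   sensitivity-consistency rule (heterogeneity/pleiotropy exclusion);
4. exposure -> mediator MR over the screened pairs;
5. two-step mediation (product of coefficients, proportion mediated,
   direction screen) for nominally significant pairs;
6. multivariable MR of the screened exposures jointly;
7. reverse MR (outcome as exposure) per exposure;
8. SMR + HEIDI gene screen over supplied cis loci;
9. nearest-gene annotation of mediator instruments.

Each stage writes a TSV into the output directory; failures are isolated
per stage (and per trait pair) and recorded in ``manifest.json`` together
with seeds, thresholds, input hashes, and versions, so that every emitted
number is reproducible by calling the owning module with the recorded
inputs.  Benjamini-Hochberg adjusted columns are emitted alongside nominal
p-values for transparency; screening itself is nominal.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as _sps

from . import __version__
from .estimators import EstimatorError, egger, ivw_from_hset, mvmr_ivw, weighted_median, wald_ratios
from .instruments import IVConfig, LDMatrix
from .mediation import StepFailure, reverse_mr, reverse_pass, two_step_mediation
from .presso import pleiotropy_report, run_presso
from .simulate import read_locus
from .smr import smr_screen
from .sumstats import harmonize, nearest_gene_table, read_bed, read_sumstats

__all__ = ["PipelineConfig", "ScreenPolicy", "run_pipeline", "screen_significant"]


@dataclasses.dataclass(frozen=True)
class ScreenPolicy:
    """Significance screening policy: IVW p below ``alpha`` plus an
    any-fail exclusion over the sensitivity tests (Q, Egger intercept,
    PRESSO global) at the same level."""

    alpha: float = 0.05
    require_sensitivity: bool = True


@dataclasses.dataclass
class PipelineConfig:
    """File paths and settings for a full pipeline run.

    ``exposures`` and ``mediators`` map trait names to summary-statistics
    paths; ``loci`` maps gene ids to ``(eqtl_tsv, ld_txt)`` pairs.  Seeds
    for every stochastic component derive from ``seed``.
    """

    exposures: dict[str, str]
    outcome: str
    out_dir: str
    mediators: dict[str, str] = dataclasses.field(default_factory=dict)
    loci: dict[str, tuple[str, str]] = dataclasses.field(default_factory=dict)
    genes_bed: str | None = None
    ld: str | None = None
    iv: IVConfig = dataclasses.field(default_factory=IVConfig)
    policy: ScreenPolicy = dataclasses.field(default_factory=ScreenPolicy)
    n_boot: int = 1000
    n_sim: int = 1000
    heidi_threshold: float = 0.01
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        iv = IVConfig(**raw.pop("iv", {}))
        policy = ScreenPolicy(**raw.pop("policy", {}))
        loci = {g: tuple(v) for g, v in raw.pop("loci", {}).items()}
        return cls(iv=iv, policy=policy, loci=loci, **raw)

    def validate(self) -> None:
        paths = [self.outcome, *self.exposures.values(), *self.mediators.values()]
        if self.genes_bed:
            paths.append(self.genes_bed)
        if self.ld:
            paths.append(self.ld)
        for g, (a, b) in self.loci.items():
            paths += [a, b]
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input file(s): {missing}")


def _bh(p: pd.Series) -> np.ndarray:
    return _sps.false_discovery_control(p.fillna(1.0).to_numpy(), method="bh")


def screen_significant(rows: pd.DataFrame, policy: ScreenPolicy | None = None) -> pd.DataFrame:
    """Pure screening of a forest table: retain IVW rows with p < alpha
    whose sensitivity flags all pass (heterogeneity / Egger intercept /
    PRESSO global each at alpha); pairs failing any sensitivity test are
    excluded when ``require_sensitivity`` is set."""
    policy = policy or ScreenPolicy()
    a = policy.alpha
    df = rows.copy()
    df["sig"] = df["pval"] < a
    for col, flag in (("q_pval", "q_pass"), ("intercept_pval", "egger_pass"),
                      ("presso_global_pval", "presso_pass")):
        if col in df.columns:
            df[flag] = df[col].isna() | (df[col] >= a)
        else:
            df[flag] = True
    df["sensitivity_pass"] = df["q_pass"] & df["egger_pass"] & df["presso_pass"]
    keep = df["sig"] & (df["sensitivity_pass"] if policy.require_sensitivity else True)
    return df[keep].reset_index(drop=True)


def _mr_with_sensitivity(name, exp_df, out_name, out_df, ld, iv, seed, n_boot, n_sim):
    chosen = iv.select(exp_df, ld).records
    if len(chosen) == 0:
        raise StepFailure(f"no instruments for {name}")
    h = harmonize(chosen, out_df)
    if h.n_snp == 0:
        raise StepFailure(f"no harmonized SNPs for {name}->{out_name}")
    gx, sx, gy, sy = h.arrays()
    ivw = ivw_from_hset(gx, sx, gy, sy, exposure=name, outcome=out_name)
    row = ivw.as_row()
    try:
        eg = egger(gx, sx, gy, sy)
        row["egger_beta"], row["egger_pval"] = eg.beta, eg.pval
        row["egger_intercept"], row["intercept_pval"] = eg.egger_intercept, eg.intercept_pval
    except EstimatorError:
        row["egger_beta"] = row["egger_pval"] = None
        row["egger_intercept"] = row["intercept_pval"] = None
    try:
        r, s = wald_ratios(gx, sx, gy, sy)
        wm = weighted_median(r, s, n_boot=n_boot, seed=seed)
        row["wmedian_beta"], row["wmedian_pval"] = wm.beta, wm.pval
    except EstimatorError:
        row["wmedian_beta"] = row["wmedian_pval"] = None
    try:
        pr = run_presso(gx, sx, gy, sy, snps=h.df["snp"], n_sim=n_sim, seed=seed)
        row["presso_global_pval"] = pr.global_pval
        row["presso_outliers"] = ",".join(pr.outlier_ids)
    except ValueError:
        row["presso_global_pval"] = None
        row["presso_outliers"] = ""
    return row, h


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the report directory.

    Stage failures isolate: a failed trait pair or a missing optional input
    skips its stage with a manifest note and does not abort the run.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_seeds = np.random.SeedSequence(config.seed).spawn(8)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in rng_seeds]
    manifest: dict = {
        "version": __version__, "seed": config.seed,
        "iv": dataclasses.asdict(config.iv),
        "policy": dataclasses.asdict(config.policy),
        "n_boot": config.n_boot, "n_sim": config.n_sim,
        "heidi_threshold": config.heidi_threshold,
        "inputs": _input_hashes(config), "stages": {},
    }

    ld = LDMatrix.from_file(config.ld) if config.ld else None
    outcome_df, _ = read_sumstats(config.outcome)
    exposures = {n: read_sumstats(p)[0] for n, p in config.exposures.items()}
    mediators = {n: read_sumstats(p)[0] for n, p in config.mediators.items()}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            entry = {"status": "ok"}
            try:
                entry.update(fn() or {})
            except Exception as exc:  # stage isolation
                entry = {"status": "error", "error": f"{type(exc).__name__}: {exc}"}
            entry["wall_s"] = round(time.perf_counter() - t0, 3)
            manifest["stages"][name] = entry
            return entry

        return deco

    forest_rows: list[dict] = []
    mediator_rows: list[dict] = []
    med_instruments: dict[str, pd.DataFrame] = {}

    @stage("exposure_outcome_mr")
    def _():
        errors = {}
        for name, df in exposures.items():
            try:
                row, _h = _mr_with_sensitivity(name, df, "outcome", outcome_df,
                                               ld, config.iv, seeds[0],
                                               config.n_boot, config.n_sim)
                forest_rows.append(row)
            except (StepFailure, EstimatorError) as exc:
                errors[name] = str(exc)
        tab = pd.DataFrame(forest_rows)
        if len(tab):
            tab["pval_bh"] = _bh(tab["pval"])
        tab.to_csv(out / "exposure_outcome_mr.tsv", sep="\t", index=False)
        return {"n_rows": len(tab), "pair_errors": errors}

    @stage("mediator_outcome_mr")
    def _():
        if not mediators:
            return {"status": "skipped", "note": "no mediator files configured"}
        errors = {}
        for name, df in mediators.items():
            try:
                row, h = _mr_with_sensitivity(name, df, "outcome", outcome_df,
                                              ld, config.iv, seeds[1],
                                              config.n_boot, config.n_sim)
                mediator_rows.append(row)
                med_instruments[name] = h.df
            except (StepFailure, EstimatorError) as exc:
                errors[name] = str(exc)
        tab = pd.DataFrame(mediator_rows)
        if len(tab):
            tab["pval_bh"] = _bh(tab["pval"])
        tab.to_csv(out / "mediator_outcome_mr.tsv", sep="\t", index=False)
        return {"n_rows": len(tab), "pair_errors": errors}

    sig_exp: list[str] = []
    sig_med: list[str] = []

    @stage("screen")
    def _():
        kept_e = screen_significant(pd.DataFrame(forest_rows), config.policy) \
            if forest_rows else pd.DataFrame(columns=["exposure"])
        kept_m = screen_significant(pd.DataFrame(mediator_rows), config.policy) \
            if mediator_rows else pd.DataFrame(columns=["exposure"])
        sig_exp.extend(kept_e["exposure"].tolist())
        sig_med.extend(kept_m["exposure"].tolist())
        kept_e.to_csv(out / "screened_exposures.tsv", sep="\t", index=False)
        kept_m.to_csv(out / "screened_mediators.tsv", sep="\t", index=False)
        return {"n_exposures": len(sig_exp), "n_mediators": len(sig_med)}

    pair_rows: list[dict] = []

    @stage("exposure_mediator_mr")
    def _():
        if not mediators:
            return {"status": "skipped", "note": "no mediator files configured"}
        errors = {}
        for e in (sig_exp or exposures):
            for m_ in (sig_med or mediators):
                try:
                    row, _h = _mr_with_sensitivity(e, exposures[e], m_,
                                                   mediators[m_], ld, config.iv,
                                                   seeds[2], config.n_boot,
                                                   config.n_sim)
                    pair_rows.append(row)
                except (StepFailure, EstimatorError) as exc:
                    errors[f"{e}->{m_}"] = str(exc)
        tab = pd.DataFrame(pair_rows)
        tab.to_csv(out / "exposure_mediator_mr.tsv", sep="\t", index=False)
        return {"n_rows": len(tab), "pair_errors": errors}

    @stage("mediation")
    def _():
        if not mediators:
            return {"status": "skipped", "note": "no mediator files configured"}
        rows = []
        errors = {}
        sig_pairs = [(r["exposure"], r["outcome"]) for r in pair_rows
                     if r["pval"] < config.policy.alpha]
        for e, m_ in sig_pairs:
            try:
                res = two_step_mediation(exposures[e], mediators[m_],
                                         outcome_df, ld, config.iv)
                try:
                    rev = reverse_mr(outcome_df, exposures[e], ld, config.iv)
                    res.reverse_pval = rev.pval
                except StepFailure:
                    pass
                row = {"exposure": e, "mediator": m_, "outcome": "outcome"}
                row.update(res.as_row())
                row["reverse_pass"] = (reverse_pass(res.total) if res.reverse_pval is None
                                       else res.reverse_pval >= config.policy.alpha)
                rows.append(row)
            except (StepFailure, EstimatorError) as exc:
                errors[f"{e}->{m_}"] = str(exc)
        tab = pd.DataFrame(rows)
        if len(tab) and "direction_pass" in tab.columns:
            tab = tab[tab["direction_pass"]].reset_index(drop=True)
        tab.to_csv(out / "mediation.tsv", sep="\t", index=False)
        return {"n_rows": len(tab), "pair_errors": errors}

    @stage("mvmr")
    def _():
        names = sig_exp or list(exposures)
        if len(names) < 2:
            return {"status": "skipped", "note": "fewer than 2 exposures to model jointly"}
        union: set[str] = set()
        for n in names:
            union |= set(config.iv.select(exposures[n], ld).records["snp"])
        base = exposures[names[0]]
        sub = base[base["snp"].isin(union)]
        h = harmonize(sub, outcome_df)
        betas = {names[0]: h.df["gamma_x"]}
        merged = h.df[["snp", "gamma_y", "se_y"]].copy()
        for n in names[1:]:
            other = exposures[n].set_index("snp")
            merged[n] = other.reindex(merged["snp"])["beta"].to_numpy()
        merged = merged.dropna()
        X = np.column_stack([h.df.set_index("snp").loc[merged["snp"], "gamma_x"]]
                            + [merged[n] for n in names[1:]])
        ests = mvmr_ivw(X, merged["gamma_y"], merged["se_y"], names=names,
                        outcome="outcome")
        tab = pd.DataFrame([e.as_row() for e in ests])
        tab.to_csv(out / "mvmr.tsv", sep="\t", index=False)
        return {"n_rows": len(tab)}

    @stage("reverse_mr")
    def _():
        rows = []
        errors = {}
        for name, df in exposures.items():
            try:
                est = reverse_mr(outcome_df, df, ld, config.iv)
                row = est.as_row()
                row.update({"exposure": "outcome", "outcome": name,
                            "reverse_pass": reverse_pass(est,
                                                         config.policy.alpha)})
                rows.append(row)
            except (StepFailure, EstimatorError) as exc:
                errors[name] = str(exc)
        pd.DataFrame(rows).to_csv(out / "reverse_mr.tsv", sep="\t", index=False)
        return {"n_rows": len(rows), "pair_errors": errors}

    @stage("smr_screen")
    def _():
        if not config.loci:
            return {"status": "skipped", "note": "no cis loci configured"}
        loci = [read_locus(tsv, ldp) for tsv, ldp in config.loci.values()]
        for gid, locus in zip(config.loci, loci):
            locus.gene_id = gid
        tab = smr_screen(loci, heidi_threshold=config.heidi_threshold,
                         seed=seeds[3])
        tab.to_csv(out / "smr_screen.tsv", sep="\t", index=False)
        return {"n_rows": len(tab), "n_pass": int(tab["pass"].sum()) if len(tab) else 0}

    @stage("nearest_gene")
    def _():
        if not config.genes_bed:
            return {"status": "skipped", "note": "no gene annotation configured"}
        genes = read_bed(config.genes_bed)
        frames = []
        for name, hdf in med_instruments.items():
            t = nearest_gene_table(hdf, genes)
            t.insert(0, "mediator", name)
            frames.append(t)
        tab = pd.concat(frames) if frames else pd.DataFrame()
        tab.to_csv(out / "nearest_genes.tsv", sep="\t", index=False)
        return {"n_rows": len(tab)}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


def _input_hashes(config: PipelineConfig) -> dict[str, str]:
    paths = {"outcome": config.outcome, **{f"exposure:{k}": v for k, v in config.exposures.items()},
             **{f"mediator:{k}": v for k, v in config.mediators.items()}}
    out = {}
    for key, p in paths.items():
        h = hashlib.sha256(Path(p).read_bytes()).hexdigest()[:16]
        out[key] = f"{p}:{h}"
    return out
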
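"""End-to-end orchestration: simulation scenarios and the empirical pipeline.

``run_scenario`` reproduces one cell group of the depth-bias simulation
study: simulate datasets, build the GRM from observed (GBS-noised)
frequencies using all SNPs, fit the family GBLUP model by REML and average
the heritability estimators across datasets, reporting Monte Carlo standard
errors sd/sqrt(n).

``run_empirical_pipeline`` mirrors the field-study analysis: quality filters,
per-depth-bin GRMs with the missing-rate correction, and a REML model with a
trial fixed effect plus genomic, iid family and parent-population random
terms.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .errors import ConvergenceError, ValidationError
from .grm import compute_grm
from .snp_filters import (
    DepthBinSpec,
    PoolFrequencyMatrix,
    assign_depth_bins,
    filter_families,
    filter_snps,
    subsample_snps,
)
from .synthpool import SimulationScenario, simulate_dataset
from .varcomp import (
    FAMILY,
    GENOMIC,
    PARENT_POP,
    MixedModelSpec,
    RandomTerm,
    fit_family_gblup,
    heritabilities,
    incidence_matrix,
    reml_fit,
)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class RunConfig:
    """Every tunable across modules, in one declarative document.

    Unknown keys are rejected; `to_yaml`/`from_yaml` round-trip the fully
    populated document so each run can be reproduced from its saved config.
    """

    max_mean_depth: float = 60.0
    min_freq: float = 0.02
    max_freq: float = 0.98
    max_missing_rate: float = 0.5
    depth_bin_edges: tuple = (0.0, 10.0, 20.0, 30.0, 40.0, 60.0)
    missing_correction: bool = True
    repair_factor: float = 0.99
    ww_diag: float = 2.0
    subsample_sizes: tuple = ()
    reml_max_iter: int = 200
    reml_tol_param: float = 1e-8
    reml_tol_loglik: float = 1e-9
    reml_n_em: int = 2
    seed: int = 0

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(doc) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        doc = dict(doc)
        for key in ("depth_bin_edges", "subsample_sizes"):
            if key in doc and doc[key] is not None:
                doc[key] = tuple(doc[key])
        return cls(**doc)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc)

    def to_yaml(self, path):
        doc = asdict(self)
        doc["depth_bin_edges"] = list(self.depth_bin_edges)
        doc["subsample_sizes"] = list(self.subsample_sizes)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @property
    def reml_controls(self) -> dict:
        return dict(
            max_iter=self.reml_max_iter,
            tol_param=self.reml_tol_param,
            tol_loglik=self.reml_tol_loglik,
            n_em=self.reml_n_em,
        )


# ---------------------------------------------------------------------------
# simulation scenarios


@dataclass
class ScenarioSummary:
    """Monte Carlo summary of one simulated scenario."""

    scenario: SimulationScenario
    n_datasets: int
    n_converged: int
    estimates: pd.DataFrame          # one row per converged dataset
    means: dict                      # estimator -> MC mean
    mc_se: dict                      # estimator -> sd/sqrt(n), nan if n == 1
    mean_grm_diagonal: float

    def row(self) -> dict:
        out = {
            "n_qtl": self.scenario.n_qtl,
            "depth": self.scenario.depth,
            "n_replicates": self.scenario.n_replicates,
            "n_datasets": self.n_datasets,
            "n_converged": self.n_converged,
            "mean_grm_diagonal": self.mean_grm_diagonal,
        }
        for k in self.means:
            out[f"mean_{k}"] = self.means[k]
            out[f"se_{k}"] = self.mc_se[k]
        return out


def run_scenario(
    scenario: SimulationScenario,
    n_datasets: int = 50,
    seed: Optional[int] = None,
    max_failure_rate: float = 0.2,
    **reml_controls,
) -> ScenarioSummary:
    """Simulate, fit and summarize ``n_datasets`` replicate datasets.

    Per-dataset seeds are spawned deterministically from the root seed
    (scenario.seed unless ``seed`` is given), so scenarios can be distributed
    without changing results.  Datasets whose REML fit fails to converge are
    recorded and excluded; more than ``max_failure_rate`` failures raises.
    """
    root = scenario.seed if seed is None else seed
    children = (
        np.random.SeedSequence(root).generate_state(n_datasets, dtype=np.uint32)
        % np.uint32(2 ** 31)
    )
    rows = []
    diags = []
    n_failed = 0
    for d in range(n_datasets):
        scen_d = replace(scenario, seed=int(children[d]))
        ds = simulate_dataset(scen_d)
        grm = compute_grm(ds.obs_pool_freqs, missing_correction=False)
        fam_index = pd.Categorical(
            ds.phenotypes["family"], categories=ds.family_ids
        ).codes
        try:
            fit = fit_family_gblup(
                ds.phenotypes["value"].to_numpy(),
                fam_index,
                grm.G,
                include_family="auto" if scenario.n_replicates == 2 else False,
                **reml_controls,
            )
        except ConvergenceError:
            n_failed += 1
            log.warning("dataset %d failed to converge; excluded", d)
            continue
        est = heritabilities(fit, grm.mean_diagonal)
        rows.append(
            {
                "dataset": d,
                "h2_G": est.h2_G,
                "H2": est.H2,
                "mean_grm_diagonal": grm.mean_diagonal,
                "sigma2_g": fit.estimates[GENOMIC],
                "sigma2_f": fit.estimates.get(FAMILY, 0.0),
                "sigma2_e": fit.estimates["residual"],
            }
        )
        diags.append(grm.mean_diagonal)
    if n_datasets and n_failed / n_datasets > max_failure_rate:
        raise ConvergenceError(
            f"{n_failed}/{n_datasets} datasets failed to converge"
        )
    estimates = pd.DataFrame(rows)
    keys = ["h2_G", "H2"] if scenario.n_replicates == 2 else ["h2_G"]
    n_ok = len(estimates)
    means = {k: float(estimates[k].mean()) for k in keys}
    mc_se = {
        k: (float(estimates[k].std(ddof=1) / np.sqrt(n_ok)) if n_ok > 1 else float("nan"))
        for k in keys
    }
    return ScenarioSummary(
        scenario=scenario,
        n_datasets=n_datasets,
        n_converged=n_ok,
        estimates=estimates,
        means=means,
        mc_se=mc_se,
        mean_grm_diagonal=float(np.mean(diags)),
    )


# ---------------------------------------------------------------------------
# empirical-style pipeline


def _design_from_pheno(pheno: pd.DataFrame, family_ids: list):
    """Fixed trial design, family incidence and parent-population incidence."""
    n = len(pheno)
    if pheno["trial"].notna().any():
        Xt, _ = incidence_matrix(pheno["trial"].fillna("_none").tolist())
        X = np.hstack([np.ones((n, 1)), Xt[:, 1:]])
    else:
        X = np.ones((n, 1))
    fam_codes = pd.Categorical(pheno["family"], categories=family_ids).codes
    if (fam_codes < 0).any():
        bad = sorted(set(pheno["family"][fam_codes < 0]))
        raise ValidationError(f"phenotype families not in the GRM: {bad[:5]}")
    Zf = np.zeros((n, len(family_ids)))
    Zf[np.arange(n), fam_codes] = 1.0
    W = None
    if pheno["pop1"].notna().any() and pheno["pop2"].notna().any():
        pops = sorted(set(pheno["pop1"].dropna()) | set(pheno["pop2"].dropna()))
        pidx = {p: k for k, p in enumerate(pops)}
        W = np.zeros((n, len(pops)))
        for i, (p1, p2) in enumerate(zip(pheno["pop1"], pheno["pop2"])):
            W[i, pidx[p1]] += 1.0
            W[i, pidx[p2]] += 1.0
    return X, Zf, fam_codes, W


def fit_empirical_model(
    pheno: pd.DataFrame,
    grm,
    config: RunConfig = RunConfig(),
):
    """REML fit of trial + genomic + iid family + parent-population model.

    The iid family term is dropped automatically (with a logged notice) when
    every family has a single plot, since it is then confounded with the
    residual.
    """
    X, Zf, fam_codes, W = _design_from_pheno(pheno, grm.family_ids)
    terms = [RandomTerm(GENOMIC, Zf, grm.G)]
    counts = np.bincount(fam_codes, minlength=len(grm.family_ids))
    if counts[counts > 0].max() >= 2:
        terms.append(RandomTerm(FAMILY, Zf))
    else:
        log.info("one plot per family: iid family term dropped (confounded with residual)")
    if W is not None:
        terms.append(RandomTerm(PARENT_POP, W))
    spec = MixedModelSpec(
        y=pheno["value"].to_numpy(), X=X, random_terms=terms, **config.reml_controls
    )
    return reml_fit(spec)


def run_empirical_pipeline(
    matrix: PoolFrequencyMatrix,
    pheno: pd.DataFrame,
    config: RunConfig = RunConfig(),
) -> pd.DataFrame:
    """Filters -> per-depth-bin GRM -> REML -> heritability table.

    Returns a tidy table with one row per (depth bin, SNP set) combination:
    the full bin plus any configured random subsample sizes.
    """
    matrix, snp_report = filter_snps(
        matrix, config.max_mean_depth, config.min_freq, config.max_freq
    )
    matrix, fam_report = filter_families(matrix, config.max_missing_rate)
    log.info("filters: %s ; %s", snp_report, fam_report)
    pheno = pheno[pheno["family"].isin(matrix.family_ids)].reset_index(drop=True)
    bins = assign_depth_bins(matrix, DepthBinSpec(config.depth_bin_edges))
    rows = []
    for label, idx in bins.items():
        if len(idx) == 0:
            continue
        if len(idx) < 100:
            log.warning("depth bin %s has only %d SNPs", label, len(idx))
        sub = matrix.take_snps(idx)
        snp_sets = [("all", sub)]
        for size in config.subsample_sizes:
            if size <= sub.n_snps:
                snp_sets.append(
                    (str(size), subsample_snps(sub, size, config.seed))
                )
        for set_label, mat in snp_sets:
            grm = compute_grm(mat, missing_correction=config.missing_correction)
            fit = fit_empirical_model(pheno, grm, config)
            est = heritabilities(fit, grm.mean_diagonal, config.ww_diag)
            rows.append(
                {
                    "depth_bin": label,
                    "snp_set": set_label,
                    "n_snps": mat.n_snps,
                    "mean_grm_diagonal": grm.mean_diagonal,
                    "h2_G": est.h2_G,
                    "se_h2_G": est.se["h2_G"],
                    "h2_G_PP": est.h2_G_PP,
                    "se_h2_G_PP": est.se["h2_G_PP"],
                    "H2": est.H2,
                    "se_H2": est.se["H2"],
                }
            )
    return pd.DataFrame(rows)
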
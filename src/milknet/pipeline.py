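"""Configuration-driven end-to-end analysis pipeline.

Stages mirror the analysis order of a causal-network study on correlated
traits: simulate (or load) a pedigreed population → fit the multi-trait
latent-factor animal model → run the IC search on posterior residual
covariances at a ladder of HPD contents → orient part of the network from
prior knowledge → fit the SEM on the oriented subset → compare models by
DIC.  Every artifact is a plain-text file under the run directory and the
whole run is reproducible from (config, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from milknet import __version__
from milknet.mixed_model import (
    MCMCResult,
    ModelSpec,
    PosteriorCovarianceSamples,
    build_design_matrices,
    choose_num_factors,
    run_mcmc,
    standardize_phenotypes,
)
from milknet.network_search import (
    PDAG,
    count_ic_tests,
    hpd_interval,
    ic_skeleton,
    orient_colliders,
    posterior_partial_correlations,
    propagate_orientations,
)
from milknet.relationships import build_numerator_relationship_matrix, parse_pedigree
from milknet.sem import LambdaStructure, ModelComparison, compare_models, fit_sem
from milknet.synthetic_data import (
    CHAIN_TRAITS,
    SimulationTruth,
    StudyDesign,
    default_truth,
    read_truth,
    simulate_phenotypes_from_sem,
    simulate_population,
    write_truth,
)

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "apply_prior_knowledge_chain",
    "export_graph",
    "molar_mass_ratio",
    "molar_mass",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; YAML round-trippable."""

    traits: tuple[str, ...] = CHAIN_TRAITS
    seed: int = 0
    # simulation (ignored when pedigree/phenotype paths are given)
    design: StudyDesign = field(default_factory=StudyDesign)
    truth: SimulationTruth | None = None
    pedigree_path: str | None = None
    phenotypes_path: str | None = None
    missing_parent: str = "0"
    # multi-trait model
    k: int | None = None  # None -> PCA at pca_threshold
    pca_threshold: float = 0.90
    variance_floor: float = 0.02
    wilmink_exponent: float = 0.05
    chains: int = 4
    iterations: int = 20_000
    burn_in: int = 5_000
    thin: int = 10
    # IC search
    hpd_contents: tuple[float, ...] = (0.95, 0.90, 0.85, 0.80)
    max_cond_size: int | None = None
    # prior knowledge and SEM
    prior_knowledge_chains: tuple[tuple[str, ...], ...] = (CHAIN_TRAITS,)
    sem_k: int = 2

    def __post_init__(self) -> None:
        self.traits = tuple(self.traits)
        self.hpd_contents = tuple(self.hpd_contents)
        if any(not 0 < c < 1 for c in self.hpd_contents):
            raise ValueError("hpd contents must lie in (0, 1)")
        if list(self.hpd_contents) != sorted(self.hpd_contents, reverse=True) or len(
            set(self.hpd_contents)
        ) != len(self.hpd_contents):
            raise ValueError("hpd contents must be strictly decreasing")
        self.prior_knowledge_chains = tuple(
            tuple(c) for c in self.prior_knowledge_chains
        )
        for chain in self.prior_knowledge_chains:
            unknown = [v for v in chain if v not in self.traits]
            if unknown:
                raise ValueError(f"prior-knowledge chain references unknown traits {unknown}")
        if self.truth is None:
            self.truth = default_truth(self.traits)

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        d = self.design
        t = self.truth
        return {
            "traits": list(self.traits),
            "seed": self.seed,
            "design": {
                "n_cows": d.n_cows,
                "n_herds": d.n_herds,
                "min_cows_per_herd": d.min_cows_per_herd,
                "dim_range": list(d.dim_range),
                "n_generations": d.n_generations,
                "n_seasons": d.n_seasons,
                "n_sire_codes": d.n_sire_codes,
                "afc_mean": d.afc_mean,
                "afc_sd": d.afc_sd,
            },
            "truth": {
                "lambda_true": t.lambda_true.tolist(),
                "g0_star": t.g0_star.tolist(),
                "psi0": t.psi0.tolist(),
            },
            "pedigree_path": self.pedigree_path,
            "phenotypes_path": self.phenotypes_path,
            "missing_parent": self.missing_parent,
            "k": self.k,
            "pca_threshold": self.pca_threshold,
            "variance_floor": self.variance_floor,
            "wilmink_exponent": self.wilmink_exponent,
            "chains": self.chains,
            "iterations": self.iterations,
            "burn_in": self.burn_in,
            "thin": self.thin,
            "hpd_contents": list(self.hpd_contents),
            "max_cond_size": self.max_cond_size,
            "prior_knowledge_chains": [list(c) for c in self.prior_knowledge_chains],
            "sem_k": self.sem_k,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        payload = dict(payload)
        traits = tuple(payload.get("traits", CHAIN_TRAITS))
        design = StudyDesign(
            **{
                **payload.get("design", {}),
                **(
                    {"dim_range": tuple(payload["design"]["dim_range"])}
                    if "design" in payload and "dim_range" in payload["design"]
                    else {}
                ),
            }
        )
        truth = None
        if payload.get("truth"):
            tr = payload["truth"]
            base = default_truth(traits)
            truth = SimulationTruth(
                traits=traits,
                lambda_true=np.array(tr.get("lambda_true", base.lambda_true)),
                g0_star=np.array(tr.get("g0_star", base.g0_star)),
                psi0=np.array(tr.get("psi0", base.psi0)),
            )
        kwargs = {
            key: payload[key]
            for key in (
                "seed",
                "pedigree_path",
                "phenotypes_path",
                "missing_parent",
                "k",
                "pca_threshold",
                "variance_floor",
                "wilmink_exponent",
                "chains",
                "iterations",
                "burn_in",
                "thin",
                "max_cond_size",
                "sem_k",
            )
            if key in payload
        }
        if "hpd_contents" in payload:
            kwargs["hpd_contents"] = tuple(payload["hpd_contents"])
        if "prior_knowledge_chains" in payload:
            kwargs["prior_knowledge_chains"] = tuple(
                tuple(c) for c in payload["prior_knowledge_chains"]
            )
        return cls(traits=traits, design=design, truth=truth, **kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# small utilities exposed at the CLI
# ---------------------------------------------------------------------------

_ATOMIC = {"C": 12.011, "H": 1.008, "O": 15.999}


def molar_mass(fatty_acid: str | int) -> float:
    """Molar mass (g/mol) of a saturated even-chain fatty acid CnH2nO2."""
    if isinstance(fatty_acid, str):
        name = fatty_acid.strip().upper().lstrip("C")
        chain, _, unsat = name.partition(":")
        if unsat and int(unsat) != 0:
            raise ValueError(
                f"{fatty_acid!r} is unsaturated; only saturated species supported"
            )
        n = int(chain)
    else:
        n = int(fatty_acid)
    if n < 4 or n % 2:
        raise ValueError(f"expected an even chain length >= 4, got {n}")
    return n * _ATOMIC["C"] + 2 * n * _ATOMIC["H"] + 2 * _ATOMIC["O"]


def molar_mass_ratio(fa_a: str | int, fa_b: str | int) -> float:
    """Ratio of molar masses M(fa_a)/M(fa_b), reported to two decimals."""
    return round(molar_mass(fa_a) / molar_mass(fa_b), 2)


def export_graph(pdag: PDAG, fmt: str, path: str | Path) -> Path:
    """Write a PDAG as DOT or a TSV edge list (lossless round trip)."""
    path = Path(path)
    if fmt == "dot":
        pdag.to_dot(path)
    elif fmt == "tsv":
        pdag.to_tsv(path)
    else:
        raise ValueError(f"unknown graph format {fmt!r} (expected 'dot' or 'tsv')")
    return path


def apply_prior_knowledge_chain(pdag: PDAG, chain: tuple[str, ...]) -> PDAG:
    """Orient the consecutive edges of an ordered trait chain.

    Raises if a chain edge is absent from the graph, conflicts with an
    existing orientation, creates a directed cycle, or introduces an
    unshielded collider the search did not support.
    """
    out = pdag.copy()
    before = pdag.unshielded_colliders()
    for a, b in zip(chain[:-1], chain[1:]):
        if not out.is_adjacent(a, b):
            raise ValueError(f"prior-knowledge edge {a!r}->{b!r} absent from the graph")
        out.orient(a, b)
    if not out.directed_part_is_acyclic():
        raise ValueError(f"prior-knowledge chain {chain} creates a directed cycle")
    new = out.unshielded_colliders() - before
    if new:
        raise ValueError(
            f"prior-knowledge chain {chain} creates unshielded colliders {sorted(new)}"
        )
    return out


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig, outdir: Path) -> tuple[pd.DataFrame, Path]:
    """Simulate (or copy in) pedigree + phenotypes; write them under outdir."""
    outdir.mkdir(parents=True, exist_ok=True)
    if cfg.pedigree_path and cfg.phenotypes_path:
        ped = parse_pedigree(cfg.pedigree_path, missing_parent=cfg.missing_parent)
        phenotypes = pd.read_csv(cfg.phenotypes_path)
    else:
        rng = np.random.default_rng(cfg.seed)
        ped, covariates = simulate_population(cfg.design, rng)
        phenotypes = simulate_phenotypes_from_sem(cfg.truth, ped, covariates, rng)
        write_truth(cfg.truth, outdir / "truth.yaml")
    ped.to_frame().to_csv(outdir / "pedigree.csv", index=False)
    phenotypes.to_csv(outdir / "phenotypes.csv", index=False)
    return phenotypes, outdir / "pedigree.csv"


def _load_inputs(cfg: PipelineConfig, outdir: Path, traits) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
    """Standardized phenotypes, design matrix and A for the phenotyped animals."""
    phenotypes = pd.read_csv(outdir / "phenotypes.csv")
    ped = parse_pedigree(outdir / "pedigree.csv", missing_parent=cfg.missing_parent)
    std, _ = standardize_phenotypes(phenotypes, traits)
    X, _ = build_design_matrices(phenotypes, cfg.wilmink_exponent)
    A = build_numerator_relationship_matrix(ped)
    animals = phenotypes["animal"].astype(str).tolist()
    A_obs = A.loc[animals, animals]
    return std, X, A_obs


def stage_fit_mtm(cfg: PipelineConfig, outdir: Path) -> MCMCResult:
    """Fit the multi-trait model on all configured traits; persist samples."""
    std, X, A_obs = _load_inputs(cfg, outdir, cfg.traits)
    k = cfg.k or choose_num_factors(std[list(cfg.traits)], cfg.pca_threshold)
    spec = ModelSpec(
        traits=cfg.traits,
        k=k,
        variance_floor=cfg.variance_floor,
        wilmink_exponent=cfg.wilmink_exponent,
    )
    result = run_mcmc(
        std,
        X,
        A_obs,
        spec,
        chains=cfg.chains,
        iterations=cfg.iterations,
        burn_in=cfg.burn_in,
        thin=cfg.thin,
        seed=cfg.seed + 1,
    )
    result.samples.to_frame().to_csv(outdir / "posterior_mtm.csv", index=False)
    np.savetxt(outdir / "deviance_mtm.txt", result.deviance)
    return result


def stage_ic_search(
    cfg: PipelineConfig, outdir: Path, samples: PosteriorCovarianceSamples
) -> dict[float, PDAG]:
    """Run the IC algorithm at every configured HPD content; export graphs."""
    pcp = posterior_partial_correlations(samples, cfg.max_cond_size)
    t = len(cfg.traits)
    n_pairs, n_subsets, n_total = count_ic_tests(t)
    if cfg.max_cond_size is None and pcp.n_series != n_total:
        raise AssertionError("IC plan size mismatch")  # invariant, not user error
    pdags: dict[float, PDAG] = {}
    for content in cfg.hpd_contents:
        skeleton, record = ic_skeleton(pcp, content)
        pdag = propagate_orientations(orient_colliders(skeleton, record))
        pdags[content] = pdag
        tag = f"{int(round(content * 100)):02d}"
        export_graph(pdag, "tsv", outdir / f"pdag_{tag}.tsv")
        export_graph(pdag, "dot", outdir / f"pdag_{tag}.dot")
        _write_audit(pcp, content, outdir / f"ic_audit_{tag}.csv")
    return pdags


def _write_audit(pcp, content: float, path: Path) -> None:
    rows = []
    traits = pcp.traits
    for (i, j, S), draws in sorted(pcp.draws.items()):
        lo, hi = hpd_interval(draws, content)
        rows.append(
            (
                traits[i],
                traits[j],
                "|".join(traits[v] for v in S),
                lo,
                hi,
                "dependent" if not lo <= 0.0 <= hi else "independent",
            )
        )
    pd.DataFrame(
        rows, columns=["i", "j", "subset", "hpd_lo", "hpd_hi", "decision"]
    ).to_csv(path, index=False)


def stage_fit_sem(
    cfg: PipelineConfig, outdir: Path, pdag: PDAG
) -> tuple[LambdaStructure, MCMCResult, "object", ModelComparison]:
    """Orient by prior knowledge, fit SEM + subset multi-trait model, compare."""
    oriented = pdag
    for chain in cfg.prior_knowledge_chains:
        oriented = apply_prior_knowledge_chain(oriented, chain)
    sem_traits = tuple(
        v for v in cfg.traits if any(v in chain for chain in cfg.prior_knowledge_chains)
    )
    edges = tuple(
        (a, b) for a, b in oriented.directed_edges() if a in sem_traits and b in sem_traits
    )
    structure = LambdaStructure(sem_traits, edges)
    structure.to_tsv(outdir / "sem_structure.tsv")

    std, X, A_obs = _load_inputs(cfg, outdir, sem_traits)
    spec = ModelSpec(
        traits=sem_traits,
        k=cfg.sem_k,
        variance_floor=cfg.variance_floor,
        wilmink_exponent=cfg.wilmink_exponent,
    )
    mtm_sub = run_mcmc(
        std, X, A_obs, spec,
        chains=cfg.chains, iterations=cfg.iterations,
        burn_in=cfg.burn_in, thin=cfg.thin, seed=cfg.seed + 2,
    )
    sem_fit = fit_sem(
        std, X, A_obs, structure,
        k=cfg.sem_k, variance_floor=cfg.variance_floor,
        chains=cfg.chains, iterations=cfg.iterations,
        burn_in=cfg.burn_in, thin=cfg.thin, seed=cfg.seed + 3,
    )
    comparison = compare_models(mtm_sub, sem_fit)
    comparison.to_csv(outdir / "comparison.csv")
    (outdir / "dic.json").write_text(
        json.dumps(
            {
                "dic_mtm": comparison.dic_a,
                "pd_mtm": comparison.pd_a,
                "dic_sem": comparison.dic_b,
                "pd_sem": comparison.pd_b,
                "delta_dic": comparison.delta_dic,
            },
            indent=2,
            sort_keys=True,
        )
    )
    lam_mean = sem_fit.lambda_mean()
    lam_sd = sem_fit.lambda_sd()
    pd.DataFrame(
        [
            (p, c, lam_mean[(p, c)], lam_sd[(p, c)])
            for p, c in structure.edges
        ],
        columns=["parent", "child", "posterior_mean", "posterior_sd"],
    ).to_csv(outdir / "structural_coefficients.csv", index=False)
    return structure, mtm_sub, sem_fit, comparison


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage and write a manifest; returns the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")

    stage_simulate(cfg, outdir)
    mtm = stage_fit_mtm(cfg, outdir)
    mtm.samples.validate(floor=cfg.variance_floor)
    pdags = stage_ic_search(cfg, outdir, mtm.samples)
    top_content = cfg.hpd_contents[0]
    structure, mtm_sub, sem_fit, comparison = stage_fit_sem(
        cfg, outdir, pdags[top_content]
    )

    n_pairs, n_subsets, n_total = count_ic_tests(len(cfg.traits))
    manifest = {
        "package_version": __version__,
        "config_hash": cfg.hash(),
        "seed": cfg.seed,
        "traits": list(cfg.traits),
        "k_mtm": mtm.spec.k,
        "ic_plan": {
            "n_pairs": n_pairs,
            "n_subsets_per_pair": n_subsets,
            "n_total": n_total,
        },
        "pdags": {
            f"{c:.2f}": sorted(f"{a}|{b}|{m}" for a, b, m in pdags[c].edges())
            for c in cfg.hpd_contents
        },
        "sem_structure": [list(e) for e in structure.edges],
        "dic": {
            "mtm": comparison.dic_a,
            "sem": comparison.dic_b,
            "pd_mtm": comparison.pd_a,
            "pd_sem": comparison.pd_b,
            "delta": comparison.delta_dic,
        },
        "artifacts": sorted(p.name for p in outdir.iterdir() if p.is_file()),
    }
    # manifest lists itself among the artifacts
    manifest["artifacts"] = sorted(set(manifest["artifacts"]) | {"manifest.json"})
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
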
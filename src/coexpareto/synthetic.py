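"""Synthetic two-condition expression data with known coexpression structure.

Data are generated from a Gaussian copula: a target Spearman correlation is
converted to the Pearson correlation of the underlying multivariate normal
via 2*sin(pi*rho_s/6), so that realized rank correlations hit the requested
targets.  The generator plants

* correlated modules (all pairwise edges at a common rho),
* double-connectivity hubs (one gene with many positive and many negative
  partners, realized as a one-factor model),
* confounder triads (a driver gene inducing marginal correlation between two
  driven genes that have no direct relationship), and
* differentially expressed genes (mean shifts in the post condition),

each restricted to one condition or present in both.  Alongside the matrices
it emits a truth table (true edges per condition, confounder pairs, DE genes,
hub identities) for recovery benchmarking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .study import CONDITIONS, ExpressionStudy

PSD_EIGENVALUE_FLOOR = 1e-8


class ConfigurationError(ValueError):
    """Raised for an internally inconsistent synthetic specification."""


def spearman_to_pearson(rho_s: float) -> float:
    """Pearson correlation of a bivariate normal whose Spearman correlation
    is ``rho_s`` (Gaussian-copula calibration): 2*sin(pi*rho_s/6)."""
    rho_s = float(rho_s)
    if abs(rho_s) > 1:
        raise ValueError(f"|rho_s| must be <= 1, got {rho_s}")
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def _check_condition(label: str) -> None:
    if label not in (*CONDITIONS, "both"):
        raise ConfigurationError(f"condition must be pre/post/both, got {label!r}")


@dataclass
class PlantedModule:
    members: tuple[int, ...]
    rho_s: float
    condition: str = "both"


@dataclass
class PlantedHub:
    hub: int
    n_pos: int
    n_neg: int
    rho_s: float            # magnitude of the hub-partner Spearman correlation
    condition: str = "both"
    partners_pos: tuple[int, ...] = ()   # resolved automatically if empty
    partners_neg: tuple[int, ...] = ()


@dataclass
class ConfounderTriad:
    driver: int
    driven: tuple[int, int]
    rho_s: float
    condition: str = "both"


@dataclass
class SyntheticSpec:
    n_genes: int
    n_samples: tuple[int, int] = (58, 60)   # (pre, post)
    modules: list[PlantedModule] = field(default_factory=list)
    hubs: list[PlantedHub] = field(default_factory=list)
    triads: list[ConfounderTriad] = field(default_factory=list)
    de_genes: dict[int, float] = field(default_factory=dict)  # gene -> post-pre shift
    noise_sd: float = 1.0     # per-gene sd of log expression
    baseline_mean: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- validation & partner resolution ------------------------------------

    def _referenced_genes(self) -> set[int]:
        used: set[int] = set()
        for m in self.modules:
            used.update(m.members)
        for h in self.hubs:
            used.add(h.hub)
            used.update(h.partners_pos)
            used.update(h.partners_neg)
        for t in self.triads:
            used.add(t.driver)
            used.update(t.driven)
        used.update(self.de_genes)
        return used

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be positive")
        if any(n < 0 for n in self.n_samples):
            raise ConfigurationError("sample counts must be non-negative")
        for m in self.modules:
            _check_condition(m.condition)
            if len(set(m.members)) != len(m.members) or len(m.members) < 2:
                raise ConfigurationError(f"module members invalid: {m.members}")
            if abs(m.rho_s) >= 1:
                raise ConfigurationError("module |rho_s| must be < 1")
        for t in self.triads:
            _check_condition(t.condition)
            if len({t.driver, *t.driven}) != 3:
                raise ConfigurationError(f"triad genes must be distinct: {t}")
            if abs(t.rho_s) >= 1:
                raise ConfigurationError("triad |rho_s| must be < 1")
        for h in self.hubs:
            _check_condition(h.condition)
            if abs(h.rho_s) >= 1:
                raise ConfigurationError("hub |rho_s| must be < 1")
            if h.n_pos + h.n_neg + 1 > self.n_genes:
                raise ConfigurationError(
                    f"hub {h.hub}: n_pos + n_neg + 1 exceeds n_genes")
        self._resolve_hub_partners()
        bad = [g for g in self._referenced_genes() if not 0 <= g < self.n_genes]
        if bad:
            raise ConfigurationError(f"gene ids out of range: {sorted(bad)[:5]}")

    def _resolve_hub_partners(self) -> None:
        """Assign hub partners deterministically from unused gene ids."""
        used = self._referenced_genes()
        pool = (g for g in range(self.n_genes) if g not in used)
        for h in self.hubs:
            if h.partners_pos or h.partners_neg:
                if len(h.partners_pos) != h.n_pos or len(h.partners_neg) != h.n_neg:
                    raise ConfigurationError(
                        f"hub {h.hub}: partner lists disagree with n_pos/n_neg")
                continue
            try:
                h.partners_pos = tuple(next(pool) for _ in range(h.n_pos))
                h.partners_neg = tuple(next(pool) for _ in range(h.n_neg))
            except StopIteration:
                raise ConfigurationError(
                    f"hub {h.hub}: not enough unused genes for partners") from None

    def gene_labels(self) -> list[str]:
        width = max(4, len(str(self.n_genes - 1)))
        return [f"G{g:0{width}d}" for g in range(self.n_genes)]


@dataclass
class SyntheticTruth:
    """Planted ground truth, keyed by integer gene ids (i < j canonical)."""

    true_edges_pre: set[tuple[int, int, int]]    # (i, j, sign)
    true_edges_post: set[tuple[int, int, int]]
    confounder_pairs: set[tuple[int, int]]       # marginally correlated non-edges
    de_genes: set[int]
    hub_ids: set[int]

    def edges(self, condition: str) -> set[tuple[int, int, int]]:
        return {"pre": self.true_edges_pre, "post": self.true_edges_post}[condition]

    def edge_pairs(self, condition: str) -> set[tuple[int, int]]:
        return {(i, j) for i, j, _ in self.edges(condition)}


def _canon(i: int, j: int) -> tuple[int, int]:
    if i == j:
        raise ConfigurationError(f"self-pair for gene {i}")
    return (i, j) if i < j else (j, i)


class _PairAssignments:
    """Accumulates off-diagonal correlation entries, detecting conflicts."""

    def __init__(self) -> None:
        self.values: dict[tuple[int, int], float] = {}

    def set(self, i: int, j: int, value: float) -> None:
        key = _canon(i, j)
        old = self.values.get(key)
        if old is not None and abs(old - value) > 1e-9:
            raise ConfigurationError(
                f"conflicting correlation assignments for gene pair {key}: "
                f"{old:.6g} vs {value:.6g}")
        self.values[key] = value


def _active(condition_mask: str, condition: str) -> bool:
    return condition_mask in ("both", condition)


def assemble_target_correlation(spec: SyntheticSpec, condition: str) -> np.ndarray:
    """Target Pearson correlation matrix of the latent Gaussian for one
    condition.

    Module pairs get the converted target correlation directly.  Hubs and
    triads are one-factor structures: besides the direct hub-partner /
    driver-driven entries, the implied second-order correlations between
    partners (product of the two path correlations) are filled in, which
    keeps the matrix positive semidefinite and makes the driven pairs'
    partial correlation given the driver exactly zero.  Any residual
    indefiniteness is repaired by eigenvalue clipping and diagonal rescaling.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    pairs = _PairAssignments()
    for m in spec.modules:
        if not _active(m.condition, condition):
            continue
        r = spearman_to_pearson(m.rho_s)
        for a_idx, a in enumerate(m.members):
            for b in m.members[a_idx + 1:]:
                pairs.set(a, b, r)
    for h in spec.hubs:
        if not _active(h.condition, condition):
            continue
        r = abs(spearman_to_pearson(h.rho_s))
        signed = [(p, r) for p in h.partners_pos] + [(p, -r) for p in h.partners_neg]
        for p, rp in signed:
            pairs.set(h.hub, p, rp)
        for a_idx, (a, ra) in enumerate(signed):
            for b, rb in signed[a_idx + 1:]:
                pairs.set(a, b, ra * rb)
    for t in spec.triads:
        if not _active(t.condition, condition):
            continue
        r = spearman_to_pearson(t.rho_s)
        x, y = t.driven
        pairs.set(t.driver, x, r)
        pairs.set(t.driver, y, r)
        pairs.set(x, y, r * r)

    corr = np.eye(spec.n_genes)
    for (i, j), v in pairs.values.items():
        corr[i, j] = corr[j, i] = v
    return _nearest_psd(corr)


def _nearest_psd(corr: np.ndarray) -> np.ndarray:
    eigval = np.linalg.eigvalsh(corr)
    if eigval[0] >= PSD_EIGENVALUE_FLOOR:
        return corr
    w, v = np.linalg.eigh(corr)
    w = np.clip(w, PSD_EIGENVALUE_FLOOR, None)
    repaired = (v * w) @ v.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return repaired


def _truth_from_spec(spec: SyntheticSpec) -> SyntheticTruth:
    edges = {"pre": set(), "post": set()}
    confounders: set[tuple[int, int]] = set()

    def add_edge(cond_mask: str, i: int, j: int, sign: int) -> None:
        key = _canon(i, j)
        for c in CONDITIONS:
            if _active(cond_mask, c):
                edges[c].add((*key, sign))

    for m in spec.modules:
        s = 1 if m.rho_s > 0 else -1
        for a_idx, a in enumerate(m.members):
            for b in m.members[a_idx + 1:]:
                add_edge(m.condition, a, b, s)
    for h in spec.hubs:
        signed = [(p, 1) for p in h.partners_pos] + [(p, -1) for p in h.partners_neg]
        for p, s in signed:
            add_edge(h.condition, h.hub, p, s)
        for a_idx, (a, _) in enumerate(signed):
            for b, _ in signed[a_idx + 1:]:
                confounders.add(_canon(a, b))
    for t in spec.triads:
        s = 1 if t.rho_s > 0 else -1
        x, y = t.driven
        add_edge(t.condition, t.driver, x, s)
        add_edge(t.condition, t.driver, y, s)
        confounders.add(_canon(x, y))

    return SyntheticTruth(
        true_edges_pre=edges["pre"],
        true_edges_post=edges["post"],
        confounder_pairs=confounders,
        de_genes=set(spec.de_genes),
        hub_ids={h.hub for h in spec.hubs},
    )


def simulate(spec: SyntheticSpec) -> tuple[ExpressionStudy, SyntheticTruth]:
    """Draw one two-condition study.

    Each condition is sampled independently (no within-patient pairing):
    expression = baseline mean + noise_sd * MVN(0, target correlation), with
    DE genes' means shifted in the post condition.  Deterministic given
    ``spec.seed``.
    """
    n_pre, n_post = spec.n_samples
    if n_pre == 0 or n_post == 0:
        raise ConfigurationError("both conditions need at least one sample")
    rng = np.random.default_rng(spec.seed)
    labels = spec.gene_labels()

    baselines = spec.baseline_mean + rng.normal(0.0, 0.5, size=spec.n_genes)
    shifts = np.zeros(spec.n_genes)
    for g, delta in spec.de_genes.items():
        shifts[g] = delta

    blocks, sample_ids, condition = [], [], []
    for cond, n in zip(CONDITIONS, (n_pre, n_post)):
        corr = assemble_target_correlation(spec, cond)
        try:
            chol = np.linalg.cholesky(
                corr + 10 * PSD_EIGENVALUE_FLOOR * np.eye(spec.n_genes))
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise RuntimeError("target correlation not PSD after repair") from exc
        z = rng.standard_normal((n, spec.n_genes)) @ chol.T
        means = baselines + (shifts if cond == "post" else 0.0)
        blocks.append(means + spec.noise_sd * z)
        sample_ids.extend(f"{cond}_{k:03d}" for k in range(n))
        condition.extend([cond] * n)

    expr = pd.DataFrame(np.vstack(blocks).T, index=labels, columns=sample_ids)
    study = ExpressionStudy(expr=expr, condition=pd.Series(condition, index=sample_ids))
    return study, _truth_from_spec(spec)


# -- spec (de)serialization and output --------------------------------------

def spec_from_yaml(path: str | Path) -> SyntheticSpec:
    raw = yaml.safe_load(Path(path).read_text())
    return SyntheticSpec(
        n_genes=raw["n_genes"],
        n_samples=tuple(raw.get("n_samples", (58, 60))),
        modules=[PlantedModule(tuple(m["members"]), m["rho_s"],
                               m.get("condition", "both"))
                 for m in raw.get("modules", [])],
        hubs=[PlantedHub(h["hub"], h["n_pos"], h["n_neg"], h["rho_s"],
                         h.get("condition", "both"))
              for h in raw.get("hubs", [])],
        triads=[ConfounderTriad(t["driver"], tuple(t["driven"]), t["rho_s"],
                                t.get("condition", "both"))
                for t in raw.get("triads", [])],
        de_genes={int(k): float(v) for k, v in raw.get("de_genes", {}).items()},
        noise_sd=raw.get("noise_sd", 1.0),
        baseline_mean=raw.get("baseline_mean", 8.0),
        seed=raw.get("seed", 0),
    )


def write_truth_tsv(spec: SyntheticSpec, truth: SyntheticTruth,
                    path: str | Path) -> None:
    labels = spec.gene_labels()
    rows = [
        {"gene_i": labels[i], "gene_j": labels[j],
         "sign": "+" if s > 0 else "-", "condition": cond}
        for cond in CONDITIONS
        for i, j, s in sorted(truth.edges(cond))
    ]
    pd.DataFrame(rows, columns=["gene_i", "gene_j", "sign", "condition"]).to_csv(
        path, sep="\t", index=False)


# -- canned study designs ----------------------------------------------------

def demo_spec(seed: int = 1) -> SyntheticSpec:
    """A small study (120 genes, 60+60 samples) with structure in every
    category, used by the pipeline demo and smoke tests.

    All structure genes carry a mean shift so they enter the DE universe;
    more edges are planted post than pre (tumor-adaptation shape).
    """
    hub = PlantedHub(hub=20, n_pos=8, n_neg=6, rho_s=0.8, condition="post",
                     partners_pos=tuple(range(24, 32)),
                     partners_neg=tuple(range(32, 38)))
    structure_genes = set(range(0, 38))
    de = {g: 1.2 if g % 2 else -1.2
          for g in sorted(structure_genes | set(range(38, 50)))}
    return SyntheticSpec(
        n_genes=120,
        n_samples=(60, 60),
        modules=[
            PlantedModule((0, 1), rho_s=0.9, condition="pre"),
            PlantedModule((2, 3), rho_s=0.9, condition="pre"),
            PlantedModule((4, 5, 6, 7), rho_s=0.9, condition="pre"),
            PlantedModule((8, 9), rho_s=0.9, condition="post"),
            PlantedModule((10, 11), rho_s=0.9, condition="post"),
            PlantedModule((12, 13), rho_s=0.9, condition="post"),
            PlantedModule((14, 15), rho_s=0.9, condition="post"),
            PlantedModule((16, 17), rho_s=0.9, condition="both"),
            PlantedModule((18, 19), rho_s=0.9, condition="both"),
        ],
        hubs=[hub],
        triads=[ConfounderTriad(driver=21, driven=(22, 23), rho_s=0.8,
                                condition="pre")],
        de_genes=de,
        seed=seed,
    )


def hub_study_spec(seed: int, n_genes: int = 200, n_hubs: int = 5,
                   n_pos: int = 15, n_neg: int = 10, rho_s: float = 0.7,
                   n_per_condition: int = 100) -> SyntheticSpec:
    """Hub-recovery benchmark: ``n_hubs`` double-connectivity hubs planted in
    the post condition among otherwise independent genes."""
    hubs = [PlantedHub(hub=k, n_pos=n_pos, n_neg=n_neg, rho_s=rho_s,
                       condition="post") for k in range(n_hubs)]
    return SyntheticSpec(n_genes=n_genes,
                         n_samples=(n_per_condition, n_per_condition),
                         hubs=hubs, seed=seed)


def replication_scale_spec(seed: int, n_genes: int = 263,
                           n_per_condition: int = 18) -> SyntheticSpec:
    """A study at replication-cohort dimensions (263 genes, 18+18 samples):
    every gene carries a DE shift so the whole panel enters the network
    stage, with pair modules planted in each condition class."""
    modules = [PlantedModule((2 * k, 2 * k + 1), rho_s=0.9, condition="post")
               for k in range(12)]
    modules += [PlantedModule((24 + 2 * k, 25 + 2 * k), rho_s=0.9,
                              condition="pre") for k in range(8)]
    modules += [PlantedModule((40 + 2 * k, 41 + 2 * k), rho_s=0.9,
                              condition="both") for k in range(4)]
    de = {g: 1.5 if g % 2 else -1.5 for g in range(n_genes)}
    return SyntheticSpec(n_genes=n_genes,
                         n_samples=(n_per_condition, n_per_condition),
                         modules=modules, de_genes=de, seed=seed)


def two_cohort_specs(seed: int, n_discovery: tuple[int, int] = (60, 60),
                     n_replication: tuple[int, int] = (18, 18),
                     rho_s: float = 0.8) -> tuple[SyntheticSpec, SyntheticSpec,
                                                  set[tuple[int, int]]]:
    """Replication benchmark: 6 treatment-induced (post-only) edges planted in
    both cohorts, plus 50 post-only edges present in the discovery cohort
    only (one 10-gene module contributing 45 edges and 5 separate pairs).

    Returns (discovery spec, replication spec, replicated pair set).
    """
    replicated = [PlantedModule((2 * k, 2 * k + 1), rho_s=rho_s, condition="post")
                  for k in range(6)]
    replicated_pairs = {(2 * k, 2 * k + 1) for k in range(6)}
    discovery_only = [PlantedModule(tuple(range(12, 22)), rho_s=rho_s,
                                    condition="post")]
    discovery_only += [PlantedModule((22 + 2 * k, 23 + 2 * k), rho_s=rho_s,
                                     condition="post") for k in range(5)]
    n_genes = 32
    disc = SyntheticSpec(n_genes=n_genes, n_samples=n_discovery,
                         modules=replicated + discovery_only, seed=seed)
    repl = SyntheticSpec(n_genes=n_genes, n_samples=n_replication,
                         modules=list(replicated), seed=seed + 1_000_000)
    return disc, repl, replicated_pairs
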
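"""Synthetic data generators with known ground truth.

Every analysis stage in this package (association scans, binder calling,
qPCR arithmetic) is exercised on data from these generators, which emulate
the shape of the study inputs that cannot be bundled:

* LD-structured haplotype pools with exact population-level pairwise r^2,
  sampled into case-control GWAS genotype matrices under a logistic
  disease model (log-additive per-allele odds ratios);
* two-signal architectures in which a variant's marginal association is
  attenuated by a correlated second signal (single-SNP masking);
* log-normal mass-spectrometry intensity tables for paired forward/reverse
  label-swap DNA pulldowns with a small set of planted allele-preferential
  binders;
* qPCR threshold-cycle (Ct) tables generated from latent template amounts
  under perfectly efficient amplification (one cycle per doubling),
  including allelic assays with genomic copy-number imbalance and
  telomere / single-copy-gene plates.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, make_variant_table

__all__ = [
    "HaplotypeSpec",
    "CaseControlSpec",
    "PulldownSimSpec",
    "QpcrSimSpec",
    "HaplotypePool",
    "InfeasibleLdError",
    "make_haplotype_pool",
    "sample_genotypes",
    "simulate_case_control",
    "simulate_case_control_study",
    "make_masked_pair_scenario",
    "simulate_pulldown",
    "simulate_qpcr",
    "CaseControlData",
]


class InfeasibleLdError(ValueError):
    """An r^2 target is not achievable at the given allele frequencies."""


# ---------------------------------------------------------------------------
# haplotype pools
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeSpec:
    """Recipe for an LD-structured haplotype pool.

    ``ld_targets`` are ``(variant_i, variant_j, r2)`` triples; the target
    graph must be a forest (tree-structured LD), which is what a single
    index SNP with a set of proxies requires.  ``ld_signs`` optionally gives
    the sign of D for each target (default all positive).
    """

    variant_ids: list[str]
    allele_freqs: list[float]
    ld_targets: list[tuple[str, str, float]] = field(default_factory=list)
    ld_signs: Optional[list[int]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.variant_ids) != len(self.allele_freqs):
            raise ValueError("variant_ids and allele_freqs lengths differ")
        for p in self.allele_freqs:
            if not (0 < p <= 0.5):
                raise ValueError("allele frequencies must lie in (0, 0.5]")
        for (_, _, r2) in self.ld_targets:
            if not (0 <= r2 <= 1):
                raise ValueError("r2 targets must lie in [0, 1]")
        if self.ld_signs is not None and len(self.ld_signs) != len(self.ld_targets):
            raise ValueError("ld_signs must parallel ld_targets")


def _pair_haplotype_freqs(pA: float, pB: float, r2: float, sign: int,
                          pair: tuple[str, str]) -> float:
    """pAB for a two-locus pair hitting the r^2 target; raises if infeasible."""
    qA, qB = 1 - pA, 1 - pB
    D = sign * np.sqrt(r2) * np.sqrt(pA * qA * pB * qB)
    dmax = min(pA * qB, qA * pB) if D >= 0 else min(pA * pB, qA * qB)
    if abs(D) > dmax + 1e-12:
        raise InfeasibleLdError(
            f"r2={r2:g} (sign {sign:+d}) between {pair[0]!r} and {pair[1]!r} is "
            f"infeasible at frequencies {pA:g}/{pB:g}: |D|={abs(D):.6g} exceeds "
            f"Dmax={dmax:.6g}"
        )
    return pA * pB + D


class HaplotypePool:
    """Population of haplotypes over a set of variants.

    Represented as a tree-factorised joint distribution: each LD edge stores
    the child's allele probability conditional on the parent's allele, so
    pairwise r^2 is exact in closed form and sampling never requires
    enumerating all 2^m haplotypes.
    """

    def __init__(self, variant_ids, freqs, edges):
        # edges: dict child -> (parent, P(child=1|parent=1), P(child=1|parent=0))
        self.variant_ids = list(variant_ids)
        self.freqs = np.asarray(freqs, dtype=float)
        self._edges = dict(edges)
        self._order = self._topo_order()

    def _topo_order(self) -> list[int]:
        idx = {v: i for i, v in enumerate(self.variant_ids)}
        order, seen = [], set()
        # roots first (variants that are nobody's child), then children
        children = set(self._edges)
        for v in self.variant_ids:
            if v not in children:
                order.append(idx[v])
                seen.add(v)
        pending = dict(self._edges)
        while pending:
            progressed = False
            for child, (parent, _, _) in list(pending.items()):
                if parent in seen:
                    order.append(idx[child])
                    seen.add(child)
                    del pending[child]
                    progressed = True
            if not progressed:  # pragma: no cover - guarded at construction
                raise ValueError("LD target graph contains a cycle")
        return order

    def marginal(self, variant_id: str) -> float:
        return float(self.freqs[self.variant_ids.index(variant_id)])

    def _edge_corr(self, child: str) -> float:
        parent, p11, p10 = self._edges[child]
        pc = self.marginal(child)
        pp = self.marginal(parent)
        pAB = p11 * pp
        D = pAB - pp * pc
        return D / np.sqrt(pp * (1 - pp) * pc * (1 - pc))

    def r2(self, vi: str, vj: str) -> float:
        """Exact population r^2 (product of edge correlations along the path)."""
        parent_of = {c: p for c, (p, _, _) in self._edges.items()}

        def path_to_root(v):
            path = [v]
            while path[-1] in parent_of:
                path.append(parent_of[path[-1]])
            return path

        pi, pj = path_to_root(vi), path_to_root(vj)
        common = set(pi) & set(pj)
        if not common:
            return 0.0
        # lowest common ancestor = first shared node on vi's path
        lca = next(v for v in pi if v in common)
        r = 1.0
        for path in (pi, pj):
            for v in path[: path.index(lca)]:
                r *= self._edge_corr(v)
        return float(r * r)

    def sample_haplotypes(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` haplotypes (0/1 array, n x m) by ancestral sampling."""
        m = len(self.variant_ids)
        H = np.zeros((n, m), dtype=np.int8)
        for col in self._order:
            v = self.variant_ids[col]
            if v in self._edges:
                parent, p11, p10 = self._edges[v]
                pg = H[:, self.variant_ids.index(parent)]
                prob = np.where(pg == 1, p11, p10)
            else:
                prob = np.full(n, self.freqs[col])
            H[:, col] = rng.random(n) < prob
        return H

    def frequency_table(self, drop_zero: bool = True, max_variants: int = 16) -> pd.DataFrame:
        """Enumerate distinct haplotypes with their population frequencies."""
        m = len(self.variant_ids)
        if m > max_variants:
            raise ValueError(
                f"refusing to enumerate 2^{m} haplotypes; sample instead"
            )
        haps = np.array(np.meshgrid(*([[0, 1]] * m), indexing="ij")).reshape(m, -1).T
        freqs = np.ones(haps.shape[0])
        parent_idx = {self.variant_ids.index(c): (self.variant_ids.index(p), p11, p10)
                      for c, (p, p11, p10) in self._edges.items()}
        for col in self._order:
            a = haps[:, col]
            if col in parent_idx:
                pi, p11, p10 = parent_idx[col]
                pr = np.where(haps[:, pi] == 1, p11, p10)
            else:
                pr = np.full(haps.shape[0], self.freqs[col])
            freqs *= np.where(a == 1, pr, 1 - pr)
        tbl = pd.DataFrame(haps, columns=self.variant_ids)
        tbl["frequency"] = freqs
        if drop_zero:
            tbl = tbl[tbl["frequency"] > 0].reset_index(drop=True)
        return tbl


def make_haplotype_pool(spec: HaplotypeSpec) -> HaplotypePool:
    """Build a haplotype pool whose pairwise LD hits the spec's r^2 targets.

    The LD-target graph must be a forest; frequencies are solved in closed
    form per edge from D = r * sqrt(pA qA pB qB).  Infeasible targets raise
    :class:`InfeasibleLdError` naming the pair.
    """
    signs = spec.ld_signs or [1] * len(spec.ld_targets)
    freq = dict(zip(spec.variant_ids, spec.allele_freqs))
    edges = {}
    has_parent: set[str] = set()
    comp = {v: v for v in spec.variant_ids}  # union-find for cycle detection

    def find(v):
        while comp[v] != v:
            comp[v] = comp[comp[v]]
            v = comp[v]
        return v

    for (vi, vj, r2), sign in zip(spec.ld_targets, signs):
        for v in (vi, vj):
            if v not in freq:
                raise KeyError(f"ld target names unknown variant {v!r}")
        if find(vi) == find(vj):
            raise ValueError(
                f"LD targets must form a forest; ({vi}, {vj}) closes a cycle"
            )
        comp[find(vi)] = find(vj)
        # orient the edge so the child does not already have a parent
        parent, child = (vi, vj) if vj not in has_parent else (vj, vi)
        if child in has_parent:
            raise ValueError(
                f"cannot orient LD target ({vi}, {vj}): both variants already "
                "carry an LD constraint; express chained LD as a path of targets "
                "rooted at one index variant"
            )
        pP, pC = freq[parent], freq[child]
        pAB = _pair_haplotype_freqs(pP, pC, r2, sign, (parent, child))
        p11 = pAB / pP  # P(child=1 | parent=1)
        p10 = (pC - pAB) / (1 - pP)
        eps = 1e-12
        p11 = min(max(p11, 0.0), 1.0) if -eps < p11 < 1 + eps else p11
        p10 = min(max(p10, 0.0), 1.0) if -eps < p10 < 1 + eps else p10
        if not (0 <= p11 <= 1 and 0 <= p10 <= 1):  # pragma: no cover
            raise InfeasibleLdError(
                f"conditional allele probability out of range for ({parent}, {child})"
            )
        edges[child] = (parent, p11, p10)
        has_parent.add(child)
    return HaplotypePool(spec.variant_ids, spec.allele_freqs, edges)


def sample_genotypes(pool: HaplotypePool, n: int, seed: int,
                     variant_table: Optional[pd.DataFrame] = None) -> GenotypeMatrix:
    """Sample ``n`` diploid individuals (two independent haplotypes each)."""
    if n < 1:
        raise ValueError("need at least one individual")
    rng = np.random.default_rng(seed)
    H = pool.sample_haplotypes(2 * n, rng)
    G = H[0::2, :] + H[1::2, :]
    if variant_table is None:
        maf = np.minimum(pool.freqs, 1.0 - pool.freqs)
        variant_table = make_variant_table(pool.variant_ids, maf=maf)
    return GenotypeMatrix(
        sample_ids=[f"S{i:05d}" for i in range(n)],
        variants=variant_table,
        genotypes=G.astype(float),
    )


# ---------------------------------------------------------------------------
# case-control phenotypes
# ---------------------------------------------------------------------------

@dataclass
class CaseControlSpec:
    """Logistic disease model and sampling design.

    ``odds_ratios`` maps causal variant id -> multiplicative per-allele OR.
    In ``cohort`` mode all individuals of the supplied genotype matrix keep
    their simulated status; in ``retrospective`` mode ``n_cases`` cases and
    ``n_controls`` controls are subsampled (GWAS-style oversampling of cases).
    """

    odds_ratios: dict[str, float]
    baseline_log_odds: float = 0.0
    mode: str = "cohort"  # or "retrospective"
    n_cases: Optional[int] = None
    n_controls: Optional[int] = None
    covariate_effects: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for v, o in self.odds_ratios.items():
            if o <= 0:
                raise ValueError(f"odds ratio for {v!r} must be positive")
        if self.mode not in ("cohort", "retrospective"):
            raise ValueError("mode must be 'cohort' or 'retrospective'")
        if self.mode == "retrospective":
            if not self.n_cases or not self.n_controls:
                raise ValueError("retrospective mode needs n_cases and n_controls")
            if self.n_cases < 1 or self.n_controls < 1:
                raise ValueError("sample sizes must be >= 1")


@dataclass
class CaseControlData:
    """Genotypes with simulated phenotype (and optional covariates)."""

    genotypes: GenotypeMatrix
    phenotype: np.ndarray
    covariates: Optional[pd.DataFrame] = None
    metadata: dict = field(default_factory=dict)


def simulate_case_control(G: GenotypeMatrix, spec: CaseControlSpec) -> CaseControlData:
    """Draw case/control status from a log-additive logistic model.

    logit P(case) = baseline + sum_j log(OR_j) g_j + covariate terms.
    """
    rng = np.random.default_rng(spec.seed)
    eta = np.full(G.n_samples, spec.baseline_log_odds, dtype=float)
    for vid, orr in spec.odds_ratios.items():
        g = G.column(vid)
        if np.isnan(g).any():
            raise ValueError(f"causal variant {vid!r} has missing genotypes")
        eta += np.log(orr) * g
    cov = None
    if spec.covariate_effects:
        cov = pd.DataFrame(
            {name: rng.standard_normal(G.n_samples) for name in spec.covariate_effects}
        )
        for name, beta in spec.covariate_effects.items():
            eta += beta * cov[name].to_numpy()
    p = 1.0 / (1.0 + np.exp(-eta))
    y = (rng.random(G.n_samples) < p).astype(float)
    if spec.mode == "cohort":
        return CaseControlData(G, y, cov, {"prevalence": float(y.mean())})
    n_case_avail = int(y.sum())
    n_ctrl_avail = int((1 - y).sum())
    if spec.n_cases > n_case_avail:
        raise ValueError(
            f"requested {spec.n_cases} cases but the cohort produced {n_case_avail}"
        )
    if spec.n_controls > n_ctrl_avail:
        raise ValueError(
            f"requested {spec.n_controls} controls but the cohort produced {n_ctrl_avail}"
        )
    case_rows = rng.choice(np.flatnonzero(y == 1), size=spec.n_cases, replace=False)
    ctrl_rows = rng.choice(np.flatnonzero(y == 0), size=spec.n_controls, replace=False)
    rows = np.sort(np.concatenate([case_rows, ctrl_rows]))
    sub = G.subset_samples(rows)
    return CaseControlData(
        sub,
        y[rows],
        None if cov is None else cov.iloc[rows].reset_index(drop=True),
        {"cohort_prevalence": float(y.mean()), "cohort_n": G.n_samples},
    )


def simulate_case_control_study(
    pool: HaplotypePool,
    spec: CaseControlSpec,
    cohort_multiplier: int = 20,
) -> CaseControlData:
    """Retrospective case-control study: simulate a cohort, subsample by status.

    The cohort size is ``cohort_multiplier * (n_cases + n_controls)``; raise
    if the cohort does not contain enough cases or controls.
    """
    if spec.mode != "retrospective":
        raise ValueError("simulate_case_control_study requires retrospective mode")
    n_cohort = cohort_multiplier * (spec.n_cases + spec.n_controls)
    G = sample_genotypes(pool, n_cohort, seed=spec.seed)
    return simulate_case_control(G, spec)


def make_masked_pair_scenario(
    or_a: float = 0.8,
    or_b: float = 1.4,
    r2: float = 0.30,
    ld_sign: int = 1,
    maf_a: float = 0.19,
    maf_b: float = 0.35,
    n_cases: int = 3000,
    n_controls: int = 3000,
    seed: int = 0,
    cohort_multiplier: int = 4,
) -> CaseControlData:
    """Two-signal architecture in which variant A's marginal signal is masked.

    With positive LD between A and B and opposite-direction effects, the
    marginal (single-SNP) slope at A, beta_A + beta_B * D / (pA qA), is
    attenuated towards zero while the conditional slope given B is not — the
    pattern in which a variant looks null marginally but lights up after
    conditioning on the stronger correlated signal.  Defaults are tuned so
    the two contributions nearly cancel at A ("melanoma-like" preset:
    protective A at MAF 0.19 masked by a risk-increasing correlated B).

    Returns a :class:`CaseControlData`; if ``r2 == 0`` no masking is possible
    and a warning is recorded in the metadata instead of raising.
    """
    spec = HaplotypeSpec(
        variant_ids=["varA", "varB"],
        allele_freqs=[maf_a, maf_b],
        ld_targets=[("varA", "varB", r2)],
        ld_signs=[ld_sign],
        seed=seed,
    )
    pool = make_haplotype_pool(spec)
    cc = CaseControlSpec(
        odds_ratios={"varA": or_a, "varB": or_b},
        baseline_log_odds=0.0,
        mode="retrospective",
        n_cases=n_cases,
        n_controls=n_controls,
        seed=seed,
    )
    data = simulate_case_control_study(pool, cc, cohort_multiplier=cohort_multiplier)
    data.metadata.update({"masked_variant": "varA", "masking_variant": "varB",
                          "r2_target": r2, "ld_sign": ld_sign})
    if r2 == 0:
        data.metadata["warning"] = (
            "LD r2 is zero between the pair: marginal and conditional "
            "associations at A coincide in distribution; no masking expected"
        )
    return data


# ---------------------------------------------------------------------------
# label-swap pulldown proteomics
# ---------------------------------------------------------------------------

@dataclass
class PulldownSimSpec:
    """Paired forward/reverse label-swap pulldown with planted binders.

    ``effect`` is the true allele-oriented log2(C/G) binding preference of a
    planted binder (+effect for C-binders, -effect for G-binders);
    ``noise_sd`` is the per-run, per-channel log2-intensity noise.
    """

    n_proteins: int = 1000
    n_c_binders: int = 5
    n_g_binders: int = 0
    effect: float = 2.0
    noise_sd: float = 0.3
    background_intensity: float = 1e6
    intensity_spread_sd: float = 1.5
    competitor: str = "poly-dAdT"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_c_binders + self.n_g_binders > self.n_proteins:
            raise ValueError("planted binders exceed protein count")
        if self.effect < 0:
            raise ValueError("effect size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise sd must be positive")


def simulate_pulldown(spec: PulldownSimSpec):
    """Simulate forward and reverse label-swap runs plus truth labels.

    Returns ``(forward_run, reverse_run, truth)`` where the runs are
    :class:`~allelics.binders.PulldownRun` objects and ``truth`` is a
    DataFrame with columns ``protein_id, truth`` (truth in
    {background, C-binder, G-binder}).
    """
    from .binders import PulldownRun  # local import: avoid a module cycle

    rng = np.random.default_rng(spec.seed)
    n = spec.n_proteins
    ids = [f"P{i:05d}" for i in range(n)]
    truth = np.array(
        ["C-binder"] * spec.n_c_binders
        + ["G-binder"] * spec.n_g_binders
        + ["background"] * (n - spec.n_c_binders - spec.n_g_binders)
    )
    rng.shuffle(truth)
    delta = np.where(truth == "C-binder", spec.effect,
                     np.where(truth == "G-binder", -spec.effect, 0.0))
    base = np.log2(spec.background_intensity) + spec.intensity_spread_sd * rng.standard_normal(n)

    runs = []
    for run_id, orientation in (("fwd", "forward"), ("rev", "reverse")):
        log_c = base + delta / 2.0 + spec.noise_sd * rng.standard_normal(n)
        log_g = base - delta / 2.0 + spec.noise_sd * rng.standard_normal(n)
        intensity_c = np.exp2(log_c)
        intensity_g = np.exp2(log_g)
        # physical channels: the forward run carries the C bait in the heavy
        # channel, the reverse run swaps the labels
        if orientation == "forward":
            heavy, light = intensity_c, intensity_g
        else:
            heavy, light = intensity_g, intensity_c
        runs.append(
            PulldownRun.from_channels(
                run_id=run_id,
                orientation=orientation,
                protein_ids=ids,
                intensity_heavy=heavy,
                intensity_light=light,
                competitor=spec.competitor,
            )
        )
    truth_df = pd.DataFrame({"protein_id": ids, "truth": truth})
    return runs[0], runs[1], truth_df


# ---------------------------------------------------------------------------
# qPCR plates
# ---------------------------------------------------------------------------

@dataclass
class QpcrSimSpec:
    """Latent template amounts expanded into replicate Ct observations.

    ``levels`` is a long table (sample, target, allele, condition, template,
    amount) of latent template amounts (arbitrary positive units); each well
    observes  Ct = offset - log2(amount) + Normal(0, sd)  independently per
    replicate — i.e. perfectly efficient amplification, one cycle per
    doubling of template.
    """

    levels: pd.DataFrame
    n_replicates: int = 3
    ct_noise_sd: float = 0.0
    ct_offset: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        required = {"sample", "target", "allele", "condition", "template", "amount"}
        missing = required - set(self.levels.columns)
        if missing:
            raise ValueError(f"levels table missing columns: {sorted(missing)}")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if self.ct_noise_sd < 0:
            raise ValueError("Ct noise sd must be >= 0")
        if (self.levels["amount"] <= 0).any():
            raise ValueError("latent template amounts must be positive")

    # -- convenience constructors ------------------------------------------

    @classmethod
    def for_expression(
        cls,
        folds: dict[tuple[str, str], float],
        target: str = "TERT",
        reference: str = "GAPDH",
        reference_level: float = 1.0,
        base_level: float = 1.0,
        **kw,
    ) -> "QpcrSimSpec":
        """Expression design: ``folds`` maps (sample, condition) -> relative level."""
        rows = []
        for (sample, condition), fold in folds.items():
            rows.append(dict(sample=sample, target=target, allele=None,
                             condition=condition, template="cDNA",
                             amount=base_level * fold))
            rows.append(dict(sample=sample, target=reference, allele=None,
                             condition=condition, template="cDNA",
                             amount=reference_level))
        return cls(levels=pd.DataFrame(rows), **kw)

    @classmethod
    def for_allelic(
        cls,
        samples: dict[str, tuple[float, float]],
        conditions: Sequence[str] = ("untreated",),
        condition_folds: Optional[dict[str, float]] = None,
        target: str = "TERT_rs2736098",
        reference: str = "GAPDH",
        base_level: float = 1.0,
        **kw,
    ) -> "QpcrSimSpec":
        """Allelic-discrimination design.

        ``samples`` maps sample -> (allelic expression ratio C/G, genomic
        copy-number ratio C/G).  cDNA template splits by expression x copy
        number; genomic DNA splits by copy number alone.  ``condition_folds``
        optionally scales overall expression per condition (e.g. knockdown).
        """
        condition_folds = condition_folds or {c: 1.0 for c in conditions}
        rows = []
        for sample, (expr_ratio, copy_ratio) in samples.items():
            for condition in conditions:
                lvl = base_level * condition_folds[condition]
                # per-allele cDNA amounts: C/G = expr_ratio * copy_ratio
                rows.append(dict(sample=sample, target=target, allele="C",
                                 condition=condition, template="cDNA",
                                 amount=lvl * expr_ratio * copy_ratio))
                rows.append(dict(sample=sample, target=target, allele="G",
                                 condition=condition, template="cDNA",
                                 amount=lvl))
                rows.append(dict(sample=sample, target=reference, allele=None,
                                 condition=condition, template="cDNA",
                                 amount=base_level))
            # genomic DNA is condition-independent
            rows.append(dict(sample=sample, target=target, allele="C",
                             condition="gDNA", template="gDNA",
                             amount=base_level * copy_ratio))
            rows.append(dict(sample=sample, target=target, allele="G",
                             condition="gDNA", template="gDNA",
                             amount=base_level))
        return cls(levels=pd.DataFrame(rows), **kw)

    @classmethod
    def for_telomere(
        cls,
        relative_lengths: dict[tuple[str, str], float],
        tel_target: str = "TEL",
        scg_target: str = "SCG",
        base_level: float = 1.0,
        **kw,
    ) -> "QpcrSimSpec":
        """Telomere design: (sample, condition) -> relative telomere length."""
        rows = []
        for (sample, condition), length in relative_lengths.items():
            rows.append(dict(sample=sample, target=tel_target, allele=None,
                             condition=condition, template="gDNA",
                             amount=base_level * length))
            rows.append(dict(sample=sample, target=scg_target, allele=None,
                             condition=condition, template="gDNA",
                             amount=base_level))
        return cls(levels=pd.DataFrame(rows), **kw)


def simulate_qpcr(spec: QpcrSimSpec) -> pd.DataFrame:
    """Expand latent template amounts into a long replicate-level Ct table.

    Output columns: sample, target, allele, condition, replicate, ct, template.
    """
    rng = np.random.default_rng(spec.seed)
    reps = np.arange(1, spec.n_replicates + 1)
    expanded = spec.levels.loc[spec.levels.index.repeat(spec.n_replicates)].reset_index(drop=True)
    expanded["replicate"] = np.tile(reps, len(spec.levels))
    ct = spec.ct_offset - np.log2(expanded["amount"].to_numpy(float))
    if spec.ct_noise_sd > 0:
        ct = ct + spec.ct_noise_sd * rng.standard_normal(len(expanded))
    expanded["ct"] = ct
    return expanded[["sample", "target", "allele", "condition", "replicate", "ct", "template"]]
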
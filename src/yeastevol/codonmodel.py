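"""Goldman–Yang codon substitution models and likelihood machinery.

Implements the GY94 family used for lineage selection tests:

* one-ratio (M0), free-ratio, and two-ratio branch models (a single dN/dS
  ratio ω per branch class),
* branch-site model A (four site classes; ω2 on the foreground branches,
  free in the alternative, fixed to 1 in the null),
* likelihood-ratio tests between nested fits,
* naive empirical-Bayes posterior identification of positively selected
  sites under model A,
* Nei–Gojobori (1986) pairwise counting estimates of dN and dS, kept as an
  independent check on the maximum-likelihood ω.

The instantaneous rate from codon *i* to codon *j* is zero unless the codons
differ at exactly one position and *j* is a sense codon; otherwise it is
π_j, multiplied by κ for transitions and by ω for nonsynonymous changes.
Each branch's matrix is rescaled so one unit of branch length equals one
expected substitution per codon (averaged over site classes for the
branch-site model), so simulated and fitted branch lengths share a scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
from scipy import linalg, optimize
from scipy.stats import chi2

from .genetic_code import (
    CODON_INDEX,
    CODON_TO_AA,
    N_CODONS,
    NONSYN_STEP,
    SENSE_CODONS,
    SINGLE_STEP,
    STOP_CODONS,
    TRANSITION_STEP,
    codons_of,
)
from .trees import BranchClassTree

GAP_CODE = -1

_MISSING_CODONS = {"---", "NNN"}


# ---------------------------------------------------------------------------
# Alignment container
# ---------------------------------------------------------------------------


@dataclass
class CodonAlignment:
    """In-frame codon alignment: equal-length CDS, gaps only as full codons."""

    taxa: list[str]
    seqs: list[str]

    def __post_init__(self):
        if len(self.taxa) != len(self.seqs):
            raise ValueError("taxa/seqs length mismatch")
        if not self.seqs:
            raise ValueError("empty alignment")
        self.seqs = [s.upper() for s in self.seqs]
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
        (length,) = lengths
        if length % 3:
            raise ValueError(f"alignment length {length} not a multiple of 3")
        for name, seq in zip(self.taxa, self.seqs):
            for i in range(0, length, 3):
                codon = seq[i : i + 3]
                if codon in _MISSING_CODONS:
                    continue
                if codon in STOP_CODONS:
                    raise ValueError(f"internal stop {codon} in {name} at nt {i}")
                if codon not in CODON_INDEX and "N" not in codon and "-" not in codon:
                    raise ValueError(f"bad codon {codon!r} in {name} at nt {i}")

    @property
    def n_codons(self) -> int:
        return len(self.seqs[0]) // 3

    def encode(self) -> np.ndarray:
        """(n_taxa, n_codons) int matrix; missing/ambiguous codons = -1."""
        mat = np.full((len(self.taxa), self.n_codons), GAP_CODE, dtype=np.int32)
        for r, seq in enumerate(self.seqs):
            for c in range(self.n_codons):
                mat[r, c] = CODON_INDEX.get(seq[3 * c : 3 * c + 3], GAP_CODE)
        return mat

    def subset_taxa(self, names: list[str]) -> "CodonAlignment":
        idx = {t: i for i, t in enumerate(self.taxa)}
        return CodonAlignment(list(names), [self.seqs[idx[n]] for n in names])

    @classmethod
    def concatenate(cls, alignments: list["CodonAlignment"]) -> "CodonAlignment":
        if not alignments:
            raise ValueError("nothing to concatenate")
        taxa = alignments[0].taxa
        for aln in alignments[1:]:
            if set(aln.taxa) != set(taxa):
                raise ValueError("taxon sets differ between alignments")
        seqs = []
        for t in taxa:
            seqs.append("".join(a.seqs[a.taxa.index(t)] for a in alignments))
        return cls(list(taxa), seqs)

    @classmethod
    def from_fasta(cls, path) -> "CodonAlignment":
        from Bio import SeqIO

        taxa, seqs = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            taxa.append(rec.id)
            seqs.append(str(rec.seq))
        return cls(taxa, seqs)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for t, s in zip(self.taxa, self.seqs):
                fh.write(f">{t}\n{s}\n")


def empirical_codon_frequencies(aln: CodonAlignment, method: str = "F3x4") -> np.ndarray:
    """Codon frequencies estimated from the alignment.

    ``F3x4`` builds them from the observed nucleotide composition at each
    codon position (the usual default); ``F61`` uses observed codon counts
    with a pseudo-count; ``equal`` returns the uniform 61-vector.
    """
    if method == "equal":
        return np.full(N_CODONS, 1.0 / N_CODONS)
    mat = aln.encode()
    if method == "F61":
        counts = np.bincount(mat[mat >= 0].ravel(), minlength=N_CODONS) + 0.5
        return counts / counts.sum()
    if method != "F3x4":
        raise ValueError(f"unknown frequency method {method!r}")
    pos_freq = np.zeros((3, 4))
    nt_index = {"A": 0, "C": 1, "G": 2, "T": 3}
    for seq in aln.seqs:
        for c in range(len(seq) // 3):
            codon = seq[3 * c : 3 * c + 3]
            if codon not in CODON_INDEX:
                continue
            for k in range(3):
                pos_freq[k, nt_index[codon[k]]] += 1
    pos_freq += 0.5  # guard empty positions
    pos_freq /= pos_freq.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            pos_freq[0, nt_index[c[0]]]
            * pos_freq[1, nt_index[c[1]]]
            * pos_freq[2, nt_index[c[2]]]
            for c in SENSE_CODONS
        ]
    )
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# Rate matrices and transition probabilities
# ---------------------------------------------------------------------------


def build_rate_matrix(
    pi: np.ndarray, kappa: float, omega: float, scale: bool = True
) -> np.ndarray:
    """GY94 instantaneous rate matrix Q (61×61).

    Rows sum to zero; with ``scale=True`` Q is normalised so the expected
    substitution rate at stationarity, -Σ_i π_i q_ii, equals 1.
    """
    pi = np.asarray(pi, dtype=float)
    _validate_rate_params(pi, kappa, omega)
    Q = rate_matrix_unscaled(pi, kappa, omega)
    if scale:
        rate = expected_rate(pi, Q)
        if rate <= 0:
            raise ValueError("degenerate rate matrix (zero expected rate)")
        Q = Q / rate
    return Q


def rate_matrix_unscaled(pi: np.ndarray, kappa: float, omega: float) -> np.ndarray:
    Q = np.where(SINGLE_STEP, pi[None, :], 0.0)
    Q = Q * np.where(TRANSITION_STEP, kappa, 1.0)
    Q = Q * np.where(NONSYN_STEP, omega, 1.0)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def expected_rate(pi: np.ndarray, Q_unscaled: np.ndarray) -> float:
    return float(-pi @ np.diag(Q_unscaled))


def _validate_rate_params(pi: np.ndarray, kappa: float, omega: float) -> None:
    if kappa <= 0:
        raise ValueError(f"kappa must be > 0, got {kappa}")
    if omega < 0:
        raise ValueError(f"omega must be >= 0, got {omega}")
    if pi.shape != (N_CODONS,):
        raise ValueError(f"pi must have {N_CODONS} entries")
    if abs(pi.sum() - 1.0) > 1e-9:
        raise ValueError("codon frequencies must sum to 1")
    if (pi < 0).any():
        raise ValueError("codon frequencies must be non-negative")


def transition_probabilities(Q: np.ndarray, t: float) -> np.ndarray:
    """P(t) = exp(Qt); rows are probability distributions."""
    if t < 0:
        raise ValueError(f"branch length must be >= 0, got {t}")
    P = linalg.expm(Q * t)
    P = np.clip(P, 0.0, None)
    return P / P.sum(axis=1, keepdims=True)


class _SpectralQ:
    """Eigendecomposition of a reversible Q for cheap repeated P(t).

    With D = diag(sqrt π), S = D Q D⁻¹ is symmetric; then
    P(t) = D⁻¹ U exp(Λ t) Uᵀ D.
    """

    def __init__(self, pi: np.ndarray, Q: np.ndarray):
        sqrt_pi = np.sqrt(np.clip(pi, 1e-300, None))
        S = (sqrt_pi[:, None] * Q) / sqrt_pi[None, :]
        S = (S + S.T) / 2.0
        self.evals, U = np.linalg.eigh(S)
        self.left = U / sqrt_pi[:, None]  # D^-1 U
        self.right = (U * sqrt_pi[:, None]).T  # U^T D

    def probs(self, t: float) -> np.ndarray:
        P = (self.left * np.exp(self.evals * t)) @ self.right
        return np.clip(P, 0.0, None)


# Decomposition cache: optimisers perturb one parameter at a time, so most
# (κ, ω) combinations repeat across likelihood evaluations.
from collections import OrderedDict  # noqa: E402

_SPECTRAL_CACHE: OrderedDict = OrderedDict()
_SPECTRAL_CACHE_MAX = 512


def _spectral(pi: np.ndarray, kappa: float, omega: float) -> tuple[_SpectralQ, float]:
    key = (pi.tobytes(), kappa, omega)
    hit = _SPECTRAL_CACHE.get(key)
    if hit is None:
        Qu = rate_matrix_unscaled(pi, kappa, omega)
        hit = (_SpectralQ(pi, Qu), expected_rate(pi, Qu))
        _SPECTRAL_CACHE[key] = hit
        if len(_SPECTRAL_CACHE) > _SPECTRAL_CACHE_MAX:
            _SPECTRAL_CACHE.popitem(last=False)
    else:
        _SPECTRAL_CACHE.move_to_end(key)
    return hit


# ---------------------------------------------------------------------------
# Model specification and fits
# ---------------------------------------------------------------------------

MODEL_IDS = ("M0", "free", "branch", "branch-site-alt", "branch-site-null")


@dataclass
class GY94Params:
    """Parameters of a fitted (or simulated) GY94-family model."""

    kappa: float
    pi: np.ndarray
    omega_by_class: dict[int, float] | None = None  # branch/free models
    omega0: float | None = None  # branch-site site class 0
    omega2: float | None = None  # branch-site foreground class
    p0: float | None = None
    p1: float | None = None

    @property
    def p2a(self) -> float | None:
        if self.p0 is None:
            return None
        p2 = 1.0 - self.p0 - self.p1
        denom = self.p0 + self.p1
        return p2 * self.p0 / denom if denom > 0 else p2 / 2

    @property
    def p2b(self) -> float | None:
        if self.p0 is None:
            return None
        p2 = 1.0 - self.p0 - self.p1
        denom = self.p0 + self.p1
        return p2 * self.p1 / denom if denom > 0 else p2 / 2


@dataclass
class ModelFit:
    model: str
    lnL: float
    params: GY94Params
    tree: BranchClassTree
    branch_omegas: dict[int, float] | None = None  # free-ratio: branch index -> ω̂
    converged: bool = True
    n_iter: int = 0
    n_starts: int = 1


@dataclass
class LRTResult:
    stat: float
    df: int
    p: float
    significant: bool


#: χ²(1) significance boundary at α = 0.05, printed to two decimals (3.84).
def lrt_threshold(df: int = 1, alpha: float = 0.05) -> float:
    return float(chi2.ppf(1.0 - alpha, df))


def lrt(fit_alt: ModelFit, fit_null: ModelFit, df: int, alpha: float = 0.05) -> LRTResult:
    """Likelihood-ratio test of nested fits: 2ΔlnL against χ²(df)."""
    if df < 1:
        raise ValueError("df must be >= 1")
    stat = 2.0 * (fit_alt.lnL - fit_null.lnL)
    if stat < -1e-4:
        raise ValueError(
            f"alternative lnL below null lnL by {-stat/2:.6g}: arguments swapped?"
        )
    stat = max(stat, 0.0)
    p = float(chi2.sf(stat, df))
    return LRTResult(stat=stat, df=df, p=p, significant=p < alpha)


# ---------------------------------------------------------------------------
# Likelihood core
# ---------------------------------------------------------------------------


def _compress_patterns(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Collapse identical alignment columns. Returns (patterns, counts, site->pattern)."""
    cols, inverse, counts = np.unique(
        mat.T, axis=0, return_inverse=True, return_counts=True
    )
    return cols.T, counts.astype(float), inverse


class _Pruner:
    """Felsenstein pruning over the 61 codon states for one alignment/tree."""

    def __init__(self, aln: CodonAlignment, tree: BranchClassTree):
        names = set(aln.taxa)
        leaf_names = set(tree.leaf_names())
        if names != leaf_names:
            missing = sorted(leaf_names - names) + sorted(names - leaf_names)
            raise ValueError(f"taxa do not match tree leaves; offenders: {missing}")
        self.tree = tree
        order = tree.leaf_names()
        mat = aln.subset_taxa(order).encode()
        self.patterns, self.counts, self.site_to_pattern = _compress_patterns(mat)
        self.n_patterns = self.patterns.shape[1]
        self.leaf_row = {name: i for i, name in enumerate(order)}

    def pattern_loglik(
        self, pi: np.ndarray, branch_P: dict[int, np.ndarray]
    ) -> np.ndarray:
        """Per-pattern log site likelihood; branch_P maps id(node) -> P matrix."""
        npat = self.n_patterns
        logscale = np.zeros(npat)
        partial: dict[int, np.ndarray] = {}
        for node in self.tree.root.postorder():
            if node.is_leaf:
                codes = self.patterns[self.leaf_row[node.name]]
                L = np.zeros((npat, N_CODONS))
                obs = codes >= 0
                L[obs, codes[obs]] = 1.0
                L[~obs, :] = 1.0  # missing data
            else:
                L = np.ones((npat, N_CODONS))
                for child in node.children:
                    P = branch_P[id(child)]
                    L *= partial.pop(id(child)) @ P.T
                mx = L.max(axis=1)
                mx[mx == 0] = 1.0
                L /= mx[:, None]
                logscale += np.log(mx)
            partial[id(node)] = L
        root_L = partial[id(self.tree.root)] @ pi
        return np.log(np.clip(root_L, 1e-300, None)) + logscale

    def loglik(self, pi: np.ndarray, branch_P: dict[int, np.ndarray]) -> float:
        return float(self.pattern_loglik(pi, branch_P) @ self.counts)


def _branch_probs_single_class(
    pruner: _Pruner,
    pi: np.ndarray,
    kappa: float,
    omega_of_branch,
) -> dict[int, np.ndarray]:
    """P(t) per branch when each branch evolves under one ω (branch models)."""
    out = {}
    for b in pruner.tree.branches():
        spec, rate = _spectral(pi, kappa, omega_of_branch(b))
        out[id(b)] = spec.probs(b.length / rate)
    return out


def log_likelihood(
    aln: CodonAlignment,
    tree: BranchClassTree,
    params: GY94Params,
    model: str,
    branch_omegas: dict[int, float] | None = None,
) -> float:
    """Log-likelihood of the alignment under the given model and parameters.

    ``model`` is one of :data:`MODEL_IDS`. For ``free``, ``branch_omegas``
    maps branch indices (order of ``tree.branches()``) to ω.
    """
    pruner = _Pruner(aln, tree)
    return _log_likelihood_pruned(pruner, params, model, branch_omegas)


def _log_likelihood_pruned(
    pruner: _Pruner,
    params: GY94Params,
    model: str,
    branch_omegas: dict[int, float] | None = None,
) -> float:
    pi = params.pi
    if model == "M0":
        w = params.omega_by_class[0]
        P = _branch_probs_single_class(pruner, pi, params.kappa, lambda b: w)
        return pruner.loglik(pi, P)
    if model == "branch":
        wc = params.omega_by_class
        P = _branch_probs_single_class(
            pruner, pi, params.kappa, lambda b: wc[b.branch_class]
        )
        return pruner.loglik(pi, P)
    if model == "free":
        if branch_omegas is None:
            raise ValueError("free model requires branch_omegas")
        branches = pruner.tree.branches()
        by_id = {id(b): branch_omegas[i] for i, b in enumerate(branches)}
        P = _branch_probs_single_class(pruner, pi, params.kappa, lambda b: by_id[id(b)])
        return pruner.loglik(pi, P)
    if model in ("branch-site-alt", "branch-site-null"):
        logliks, props = _branch_site_class_logliks(pruner, params)
        mix = _logsumexp_weighted(logliks, props)
        return float(mix @ pruner.counts)
    raise ValueError(f"unknown model {model!r}")


_BS_CLASSES = ("0", "1", "2a", "2b")


def _branch_site_omegas(params: GY94Params) -> dict[str, dict[int, float]]:
    """Site class -> branch class -> ω for branch-site model A."""
    w0, w2 = params.omega0, params.omega2
    return {
        "0": {0: w0, 1: w0},
        "1": {0: 1.0, 1: 1.0},
        "2a": {0: w0, 1: w2},
        "2b": {0: 1.0, 1: w2},
    }


def _branch_site_class_logliks(
    pruner: _Pruner, params: GY94Params
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site-class per-pattern log likelihood matrix and class proportions.

    Every branch uses a single scaling factor equal to the mixture-expected
    substitution rate on that branch, so branch lengths remain in expected
    substitutions per codon.
    """
    pi, kappa = params.pi, params.kappa
    props = np.array([params.p0, params.p1, params.p2a, params.p2b])
    class_w = _branch_site_omegas(params)
    distinct = sorted({w for m in class_w.values() for w in m.values()})
    spectral = {}
    rate = {}
    for w in distinct:
        spectral[w], rate[w] = _spectral(pi, kappa, w)
    # per-branch-class mixture rate
    mix_rate = {
        bc: sum(p * rate[class_w[c][bc]] for p, c in zip(props, _BS_CLASSES))
        for bc in (0, 1)
    }
    logliks = np.empty((4, pruner.n_patterns))
    for ci, cname in enumerate(_BS_CLASSES):
        branch_P = {}
        for b in pruner.tree.branches():
            w = class_w[cname][b.branch_class]
            branch_P[id(b)] = spectral[w].probs(b.length / mix_rate[b.branch_class])
        logliks[ci] = pruner.pattern_loglik(pi, branch_P)
    return logliks, props


def _logsumexp_weighted(logliks: np.ndarray, props: np.ndarray) -> np.ndarray:
    logw = np.log(np.clip(props, 1e-300, None))[:, None]
    a = logliks + logw
    mx = a.max(axis=0)
    return mx + np.log(np.exp(a - mx).sum(axis=0))


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -35, 35)))


def _logit(p: float) -> float:
    p = min(max(p, 1e-6), 1 - 1e-6)
    return math.log(p / (1 - p))


_KAPPA0, _OMEGA0 = 2.0, 0.4
_T_MIN, _T_MAX = 1e-6, 25.0
_W_MIN, _W_MAX = 1e-4, 100.0


def fit_model(
    aln: CodonAlignment,
    tree: BranchClassTree,
    model: str,
    *,
    pi: np.ndarray | None = None,
    freq_method: str = "F3x4",
    optimize_branch_lengths: bool | None = None,
    n_starts: int = 3,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
    warm_start: GY94Params | None = None,
) -> ModelFit:
    """Maximise the log-likelihood of ``model`` on ``aln`` over ``tree``.

    Branch lengths are optimised jointly for M0 (the default first-stage fit)
    and held fixed for the branch, free-ratio and branch-site fits unless
    ``optimize_branch_lengths`` overrides this. Multi-start bounded
    quasi-Newton (L-BFGS-B) on log/logit-transformed parameters.
    """
    if model not in MODEL_IDS:
        raise ValueError(f"unknown model {model!r}; choose from {MODEL_IDS}")
    if model != "M0" and len(aln.taxa) < 3:
        raise ValueError(f"{model} model needs >= 3 taxa")
    if pi is None:
        pi = empirical_codon_frequencies(aln, freq_method)
    tree = tree.copy()
    if optimize_branch_lengths is None:
        optimize_branch_lengths = model == "M0"
    branches = tree.branches()
    n_br = len(branches)
    classes = sorted(tree.branch_classes())
    if model in ("branch", "branch-site-alt", "branch-site-null") and classes != [0, 1]:
        raise ValueError(f"branch classes must be {{0,1}}, tree has {classes}")

    pruner = _Pruner(aln, tree)
    rng = np.random.default_rng(seed)

    def unpack(x: np.ndarray) -> tuple[GY94Params, dict[int, float] | None]:
        i = 0
        kappa = math.exp(x[i]); i += 1
        if optimize_branch_lengths:
            for b, xb in zip(branches, x[i : i + n_br]):
                b.length = math.exp(xb)
            i += n_br
        branch_omegas = None
        if model == "M0":
            params = GY94Params(kappa, pi, omega_by_class={0: math.exp(x[i])})
        elif model == "branch":
            params = GY94Params(
                kappa, pi,
                omega_by_class={c: math.exp(x[i + k]) for k, c in enumerate(classes)},
            )
        elif model == "free":
            branch_omegas = {k: math.exp(x[i + k]) for k in range(n_br)}
            params = GY94Params(kappa, pi, omega_by_class=None)
        else:  # branch-site
            w0 = float(_sigmoid(x[i]))
            w2 = 1.0 if model == "branch-site-null" else 1.0 + math.exp(x[i + 1])
            j = i + (1 if model == "branch-site-null" else 2)
            ea, eb = math.exp(min(x[j], 35)), math.exp(min(x[j + 1], 35))
            denom = 1.0 + ea + eb
            params = GY94Params(
                kappa, pi, omega0=w0, omega2=w2, p0=ea / denom, p1=eb / denom
            )
        return params, branch_omegas

    def neg_loglik(x: np.ndarray) -> float:
        params, bw = unpack(x)
        try:
            return -_log_likelihood_pruned(pruner, params, model, bw)
        except (ValueError, FloatingPointError):  # pragma: no cover
            return 1e12

    def start_vector(jitter: bool) -> np.ndarray:
        parts = [math.log(_KAPPA0)]
        if optimize_branch_lengths:
            parts += [math.log(max(b.length, 0.05)) for b in branches]
        if model == "M0":
            parts += [math.log(_OMEGA0)]
        elif model == "branch":
            parts += [math.log(_OMEGA0)] * len(classes)
        elif model == "free":
            parts += [math.log(_OMEGA0)] * n_br
        else:
            parts += [_logit(0.3)]
            if model == "branch-site-alt":
                parts += [math.log(1.0)]  # omega2 = 2
            parts += [math.log(0.6 / 0.25), math.log(0.15 / 0.25)]
        x0 = np.array(parts)
        if jitter:
            x0 = x0 + rng.normal(0.0, 0.7, size=x0.shape)
        return x0

    lo, hi = [], []
    idx = 1 + (n_br if optimize_branch_lengths else 0)
    lo.append(math.log(0.05)); hi.append(math.log(99.0))
    if optimize_branch_lengths:
        lo += [math.log(_T_MIN)] * n_br
        hi += [math.log(_T_MAX)] * n_br
    if model in ("M0", "branch", "free"):
        n_rest = len(start_vector(False)) - idx
        lo += [math.log(_W_MIN)] * n_rest
        hi += [math.log(_W_MAX)] * n_rest
    else:
        lo += [-30.0]; hi += [30.0]  # logit ω0
        if model == "branch-site-alt":
            lo += [-30.0]; hi += [math.log(_W_MAX - 1.0)]  # log(ω2 - 1)
        lo += [-30.0, -30.0]; hi += [30.0, 30.0]  # proportion logits
    bounds = list(zip(lo, hi))

    starts = [start_vector(jitter=False)]
    if (
        warm_start is not None
        and not optimize_branch_lengths
        and model in ("branch-site-alt", "branch-site-null")
    ):
        w2 = warm_start.omega2 if model == "branch-site-alt" else None
        parts = [math.log(warm_start.kappa), _logit(warm_start.omega0)]
        if model == "branch-site-alt":
            # nudge ω2 off the null boundary: at ω2 = 1 the gradient of the
            # log(ω2-1) coordinate vanishes and the optimiser cannot move
            parts.append(math.log(max((w2 or 1.0) - 1.0, 0.3)))
        p0 = min(max(warm_start.p0, 1e-12), 1 - 2e-12)
        p1 = min(max(warm_start.p1, 1e-12), 1 - p0 - 1e-12)
        p2 = max(1.0 - p0 - p1, 1e-12)
        parts += [math.log(p0 / p2), math.log(p1 / p2)]
        starts.append(np.array(parts))
    while len(starts) < max(1, n_starts) + (1 if warm_start is not None else 0):
        starts.append(start_vector(jitter=True))

    best = None
    total_iter = 0
    for x0 in starts:
        x0 = np.clip(x0, lo, hi)
        res = optimize.minimize(
            neg_loglik, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-7},
        )
        total_iter += res.nit
        if best is None or res.fun < best.fun:
            best = res
    if (
        warm_start is not None
        and not optimize_branch_lengths
        and model == "branch-site-alt"
    ):
        # the alternative nests the null (ω2 = 1): never return a fit below it
        null_rep = starts[1].copy()
        null_rep[2] = -30.0  # ω2 -> 1 + e^-30
        null_rep = np.clip(null_rep, lo, hi)
        f_null = neg_loglik(null_rep)
        if f_null < best.fun:
            best = optimize.OptimizeResult(
                x=null_rep, fun=f_null, success=True, nit=best.nit
            )
    params, branch_omegas = unpack(best.x)
    if optimize_branch_lengths:
        # unpack already wrote the optimal lengths into `tree`
        pass
    fit = ModelFit(
        model=model,
        lnL=float(-best.fun),
        params=params,
        tree=tree,
        branch_omegas=branch_omegas,
        converged=bool(best.success),
        n_iter=total_iter,
        n_starts=max(1, n_starts),
    )
    return fit


def fit_branch_models(
    aln: CodonAlignment,
    tree: BranchClassTree,
    *,
    models: tuple[str, ...] = ("M0", "branch"),
    n_starts: int = 3,
    seed: int = 0,
    freq_method: str = "F3x4",
    optimize_branch_lengths: bool = True,
) -> dict[str, ModelFit]:
    """Two-stage protocol: fit M0 with branch lengths, then refit the other
    requested models with those lengths held fixed."""
    pi = empirical_codon_frequencies(aln, freq_method)
    m0 = fit_model(
        aln, tree, "M0", pi=pi, n_starts=n_starts, seed=seed,
        optimize_branch_lengths=optimize_branch_lengths,
    )
    fits = {"M0": m0}
    ordered = [m for m in models if m != "M0"]
    # fit the branch-site null before the alternative so the alternative can
    # be warm-started from it (guarantees the nesting inequality numerically)
    if "branch-site-null" in ordered and "branch-site-alt" in ordered:
        ordered.remove("branch-site-null")
        ordered.insert(0, "branch-site-null")
    for model in ordered:
        warm = fits.get("branch-site-null") if model == "branch-site-alt" else None
        fits[model] = fit_model(
            aln, m0.tree, model, pi=pi, n_starts=n_starts, seed=seed + 1,
            optimize_branch_lengths=False,
            warm_start=warm.params if warm is not None else None,
        )
    return fits


# ---------------------------------------------------------------------------
# Site posteriors (naive empirical Bayes at the MLE)
# ---------------------------------------------------------------------------


@dataclass
class SitePosterior:
    site: int  # 0-based codon column
    posterior: float  # P(class 2a or 2b | data)
    flagged: bool


def site_posteriors(
    fit_alt: ModelFit,
    aln: CodonAlignment,
    tree: BranchClassTree | None = None,
    threshold: float = 0.95,
) -> list[SitePosterior]:
    """Per-site posterior probability of the positive-selection site classes
    (2a/2b) under the fitted branch-site alternative model.

    Empirical Bayes at the MLE: posterior ∝ p_c × L_c(site), normalised over
    the four site classes.
    """
    if fit_alt.model != "branch-site-alt":
        raise ValueError("site_posteriors requires a branch-site alternative fit")
    tree = tree or fit_alt.tree
    pruner = _Pruner(aln, tree)
    logliks, props = _branch_site_class_logliks(pruner, fit_alt.params)
    logw = np.log(np.clip(props, 1e-300, None))[:, None]
    a = logliks + logw
    a -= a.max(axis=0, keepdims=True)
    w = np.exp(a)
    post_pat = (w[2] + w[3]) / w.sum(axis=0)
    out = []
    for site in range(aln.n_codons):
        p = float(post_pat[pruner.site_to_pattern[site]])
        out.append(SitePosterior(site=site, posterior=p, flagged=p > threshold))
    return out


# ---------------------------------------------------------------------------
# Nei–Gojobori 1986 pairwise counting (independent of the ML path)
# ---------------------------------------------------------------------------


@dataclass
class PairwiseDnDs:
    dN: float
    dS: float
    ratio: float | None  # None when dS == 0 or saturated
    saturated: bool = False


def _codon_site_counts(codon: str) -> tuple[float, float]:
    """Synonymous / nonsynonymous site counts of one codon (stops count as
    nonsynonymous targets)."""
    syn = 0.0
    for k in range(3):
        for nt in "ACGT":
            if nt == codon[k]:
                continue
            alt = codon[:k] + nt + codon[k + 1 :]
            if alt not in STOP_CODONS and CODON_TO_AA[alt] == CODON_TO_AA[codon]:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


def _pair_differences(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged synonymous/nonsynonymous difference counts between
    two codons; pathways through stop codons are excluded when possible."""
    diff = [k for k in range(3) if c1[k] != c2[k]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff):
        cur = c1
        sd = nd = 0.0
        ok = True
        for k in order:
            nxt = cur[:k] + c2[k] + cur[k + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if CODON_TO_AA[cur] == CODON_TO_AA[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            paths.append((sd, nd))
    if not paths:  # all pathways hit a stop: count every change nonsynonymous
        return 0.0, float(len(diff))
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def _jukes_cantor(p: float) -> tuple[float, bool]:
    """JC-corrected distance; falls back to the raw proportion when p ≥ 3/4
    (saturation), flagged by the second return value."""
    if p < 0.75:
        return -0.75 * math.log(1.0 - 4.0 * p / 3.0), False
    return p, True


def pairwise_dnds_ng86(cds_a: str, cds_b: str) -> PairwiseDnDs:
    """Nei–Gojobori (1986) dN and dS for two equal-length in-frame CDS."""
    if len(cds_a) != len(cds_b):
        raise ValueError(f"length mismatch: {len(cds_a)} vs {len(cds_b)}")
    cods_a, cods_b = codons_of(cds_a.upper()), codons_of(cds_b.upper())
    S = N = Sd = Nd = 0.0
    for ca, cb in zip(cods_a, cods_b):
        if ca not in CODON_INDEX or cb not in CODON_INDEX:
            continue  # gaps / ambiguity skipped
        sa, na = _codon_site_counts(ca)
        sb, nb = _codon_site_counts(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        sd, nd = _pair_differences(ca, cb)
        Sd += sd
        Nd += nd
    if S == 0 or N == 0:
        raise ValueError("no comparable codons")
    pS, pN = Sd / S, Nd / N
    dS, sat_s = _jukes_cantor(pS)
    dN, sat_n = _jukes_cantor(pN)
    ratio = dN / dS if dS > 0 else None
    return PairwiseDnDs(dN=dN, dS=dS, ratio=ratio, saturated=sat_s or sat_n)
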
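"""Count-based statistics for the strain x treatment design.

The central object is :class:`StrainResponseModel`, a statsmodels-style
model built from an integer feature x sample count matrix and a sample
design (strain, treatment, replicate).  ``fit_interaction()`` performs the
per-gene negative-binomial likelihood-ratio test of the strain:treatment
interaction (full model ``~ strain + treatment + strain:treatment`` against
the reduced ``~ strain + treatment``); ``fit_pairwise()`` performs the
two-group NB Wald test behind the (FDR <= 0.05, >= 2-fold) expression filter
and the (FDR <= 0.001) accessibility filter.  Both return Results objects
carrying a per-feature frame and a ``summary()`` table.

Counts are modelled as NB(mu, alpha) with var = mu + alpha * mu^2.  The
gene-wise dispersion alpha is a pooled method-of-moments estimate over the
design cells of the fitted model (no shrinkage, floored at 1e-8), shared
between the full and reduced fits of the LRT.  GLMs are fitted by IRLS on
the log link (statsmodels) with log size factors as offset; fits that fail
fall back to mean-based estimates and are flagged.

Module-level functions (``size_factors_median_ratio``, ``pairwise_de``,
``interaction_lrt``, ``kmeans_profiles``, ``fano_factor``,
``synergy_score``) are thin wrappers over the model for pipeline use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

ALPHA_FLOOR = 1e-8
LFC_PSEUDOCOUNT = 1.0

TREATMENTS = ("Ctrl", "IL4", "LPS", "IL4+LPS")


class DesignError(ValueError):
    """Raised for unusable sample designs (empty cells, degenerate groups)."""


class NormalizationError(ValueError):
    """Raised when median-of-ratios normalization is undefined."""


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def size_factors_median_ratio(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    The reference is the per-gene geometric mean across samples; genes with
    any zero count are excluded from the reference.  Raises
    :class:`NormalizationError` if no gene is positive in every sample.
    """
    values = counts.to_numpy(dtype=float)
    positive = (values > 0).all(axis=1)
    if not positive.any():
        raise NormalizationError(
            "no gene with all-positive counts; size factors undefined")
    logs = np.log(values[positive])
    ref = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - ref, axis=0))
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalized_counts(counts: pd.DataFrame,
                      size_factors: pd.Series | None = None) -> pd.DataFrame:
    if size_factors is None:
        size_factors = size_factors_median_ratio(counts)
    return counts / size_factors


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------

def _pooled_dispersion(norm: np.ndarray, groups: list[np.ndarray]) -> np.ndarray:
    """Per-gene method-of-moments alpha, alpha = max((s^2 - m)/m^2, floor).

    ``s^2`` is the within-cell variance pooled across the design cells (the
    replicate scatter the model treats as noise) and ``m`` the mean of
    normalized counts over the same samples; no shrinkage.
    """
    n_genes = norm.shape[0]
    num = np.zeros(n_genes)
    den = np.zeros(n_genes)
    dof = 0
    for idx in groups:
        if len(idx) < 2:
            continue
        sub = norm[:, idx]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        w = len(idx) - 1
        # E[v - m] = alpha * m^2 within a cell; summing numerators and
        # denominators before dividing keeps the estimate consistent when
        # cell means differ (a pooled-mean version is biased upward for
        # genuinely responding genes) while sharing dof across cells
        num += w * (v - m)
        den += w * m ** 2
        dof += w
    if dof == 0:
        return np.full(n_genes, ALPHA_FLOOR)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    return np.maximum(alpha, ALPHA_FLOOR)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (limma's recipe)."""
    from scipy.special import polygamma
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(100):
        tri = float(polygamma(1, x))
        step = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += step
        if abs(step) < 1e-10 * x:
            break
    return max(x, 1e-8)


def _moderate_dispersion(alpha_hat: np.ndarray, mean_norm: np.ndarray,
                         dof: int):
    """Empirical-Bayes squeeze of per-gene dispersions.

    The per-gene quantity x = alpha + 1/mean (the squared per-sample CV the
    NB model implies on the log scale) behaves approximately like a scaled
    chi-square with ``dof`` degrees of freedom.  Following the
    limma/edgeR-QL convention, the between-gene spread of log x in excess
    of its sampling variance (trigamma(dof/2)) yields a prior dof d0; each
    gene's x is squeezed toward the common value with weight d0/(dof+d0)
    and downstream references gain ``dof + d0`` degrees of freedom.

    Returns ``(alpha_moderated, total_dof)``.
    """
    from scipy.special import digamma, polygamma
    usable = mean_norm > 0
    shot = np.where(usable, 1.0 / np.maximum(mean_norm, 1e-9), 0.0)
    x = np.maximum(alpha_hat + shot, 1e-10)
    if usable.sum() < 10:
        return alpha_hat, float(dof)
    w = np.log(x[usable])
    sampling = float(polygamma(1, dof / 2.0))
    excess = float(np.var(w, ddof=1)) - sampling
    if excess <= 1e-12:
        d0 = 1e8  # spread fully explained by sampling noise
    else:
        d0 = min(2.0 * _trigamma_inverse(excess), 1e8)
    log_x0 = float(np.mean(w)) - (float(digamma(dof / 2.0))
                                  - np.log(dof / 2.0))
    x0 = float(np.exp(log_x0))
    squeezed = (dof * x + d0 * x0) / (dof + d0)
    alpha_mod = np.maximum(squeezed - shot, ALPHA_FLOOR)
    alpha_mod[~usable] = ALPHA_FLOOR
    total_dof = float(min(dof + d0, 1e8))
    return alpha_mod, total_dof


# ---------------------------------------------------------------------------
# GLM helpers
# ---------------------------------------------------------------------------

def _fit_glm(y: np.ndarray, X: np.ndarray, offset: np.ndarray, alpha: float):
    """NB GLM by IRLS on the log link; returns the results or None."""
    fam = sm.families.NegativeBinomial(alpha=max(alpha, ALPHA_FLOOR))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=fam, offset=offset).fit(maxiter=100, tol=1e-8)
        if not np.all(np.isfinite(res.params)) or np.abs(res.params).max() > 30:
            return None
        return res
    except Exception:
        return None


def _bh(p: np.ndarray) -> np.ndarray:
    out = np.ones_like(p)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------

@dataclass
class PairwiseDEResults:
    """Per-feature NB Wald test of group B against group A."""

    frame: pd.DataFrame
    group_a: list
    group_b: list
    fdr_threshold: float
    lfc_threshold: float
    pseudocount: float = LFC_PSEUDOCOUNT

    @property
    def passing(self) -> pd.Index:
        return self.frame.index[self.frame["pass"]]

    def summary(self) -> str:
        f = self.frame
        lines = [
            "Pairwise NB Wald differential test",
            f"  group A samples : {len(self.group_a)}",
            f"  group B samples : {len(self.group_b)}",
            f"  features        : {len(f)}",
            f"  filter          : FDR <= {self.fdr_threshold:g}, "
            f"|log2FC| >= {self.lfc_threshold:g} (pseudocount {self.pseudocount:g})",
            f"  passing         : {int(f['pass'].sum())} "
            f"({int((f['pass'] & (f['lfc'] > 0)).sum())} up, "
            f"{int((f['pass'] & (f['lfc'] < 0)).sum())} down)",
            f"  fallback fits   : {int(f['fallback'].sum())}",
        ]
        return "\n".join(lines)


@dataclass
class InteractionResults:
    """Per-feature likelihood-ratio test of the strain:treatment interaction."""

    frame: pd.DataFrame
    df: int
    strains: list
    treatments: list
    fdr_threshold: float = 0.05

    def strain_specific(self, strain) -> pd.Index:
        f = self.frame
        return f.index[(f["fdr"] <= self.fdr_threshold) & (f["direction"] == strain)]

    def summary(self) -> str:
        f = self.frame
        lines = [
            "Strain x treatment NB likelihood-ratio test",
            f"  full model      : ~ strain + treatment + strain:treatment",
            f"  reduced model   : ~ strain + treatment",
            f"  df              : {self.df}",
            f"  features        : {len(f)}",
            f"  FDR <= {self.fdr_threshold:g}    : {int((f['fdr'] <= self.fdr_threshold).sum())}",
        ]
        for s in self.strains:
            lines.append(f"    direction {s:<6}: {len(self.strain_specific(s))}")
        lines.append(f"  fallback fits   : {int(f['fallback'].sum())}")
        return "\n".join(lines)


@dataclass
class ClusterResult:
    """k-means assignment of fold-change profiles under correlation distance."""

    labels: pd.Series
    centroids: np.ndarray
    objective: float
    dropped: list = field(default_factory=list)

    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()

    def summary(self) -> str:
        sizes = ", ".join(f"C{c}:{n}" for c, n in self.sizes().items())
        out = [f"k-means (correlation distance), k={len(self.centroids)}",
               f"  objective (total 1-r): {self.objective:.4f}",
               f"  cluster sizes        : {sizes}"]
        if self.dropped:
            out.append(f"  constant rows dropped: {len(self.dropped)}")
        return "\n".join(out)


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

class StrainResponseModel:
    """NB count model for a two-strain, multi-treatment design.

    Parameters
    ----------
    counts : DataFrame
        Non-negative integer feature x sample matrix.
    design : DataFrame
        One row per sample with ``strain``, ``treatment`` and ``replicate``
        columns, indexed by sample id matching the count columns.
    size_factors : Series, optional
        Precomputed per-sample factors; median-of-ratios by default.
    """

    def __init__(self, counts: pd.DataFrame, design: pd.DataFrame,
                 size_factors: pd.Series | None = None):
        if list(counts.columns) != list(design.index):
            design = design.reindex(counts.columns)
            if design.isna().any().any():
                raise DesignError("count columns and design samples disagree")
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = counts
        self.design = design
        self.size_factors = (size_factors if size_factors is not None
                             else size_factors_median_ratio(counts))
        self.size_factors = self.size_factors.reindex(counts.columns)
        self.norm = counts.to_numpy(dtype=float) / self.size_factors.to_numpy()
        self.strains = list(pd.unique(design["strain"]))
        self.treatments = list(pd.unique(design["treatment"]))

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_fixture(cls, fixture_dir) -> "StrainResponseModel":
        from . import io as sio
        import os
        design = sio.read_design(os.path.join(fixture_dir, "design.tsv"))
        counts = sio.read_counts(os.path.join(fixture_dir, "rna_counts.tsv"), design)
        return cls(counts, design)

    # -- internals ---------------------------------------------------------

    def _samples(self, group) -> list:
        """Resolve a group spec (sample list or {strain,treatment} dict)."""
        if isinstance(group, dict):
            mask = np.ones(len(self.design), dtype=bool)
            for key, val in group.items():
                if key not in self.design.columns:
                    raise DesignError(f"unknown design column {key!r}")
                if val not in set(self.design[key]):
                    raise DesignError(f"unknown {key} label {val!r}")
                mask &= (self.design[key] == val).to_numpy()
            samples = list(self.design.index[mask])
        else:
            samples = list(group)
            unknown = [s for s in samples if s not in self.design.index]
            if unknown:
                raise DesignError(f"unknown sample ids {unknown}")
        return samples

    def _group_means(self, sample_idx: np.ndarray) -> np.ndarray:
        return self.norm[:, sample_idx].mean(axis=1)

    def _design_cells(self) -> list[np.ndarray]:
        """Sample index arrays for every strain x treatment cell."""
        return [np.flatnonzero(((self.design["strain"] == s)
                                & (self.design["treatment"] == t)).to_numpy())
                for s in self.strains for t in self.treatments]

    @property
    def dispersion_dof(self) -> int:
        """Replicate degrees of freedom behind the raw dispersion estimate."""
        return int(sum(max(len(c) - 1, 0) for c in self._design_cells()))

    def _dispersions(self):
        """Moderated per-gene alphas and the total reference dof (cached)."""
        if not hasattr(self, "_disp_cache"):
            raw = _pooled_dispersion(self.norm, self._design_cells())
            mean_norm = self.norm.mean(axis=1)
            self._disp_cache = _moderate_dispersion(raw, mean_norm,
                                                    self.dispersion_dof)
        return self._disp_cache

    # -- pairwise Wald test ------------------------------------------------

    def fit_pairwise(self, group_a, group_b, fdr_threshold: float = 0.05,
                     lfc_threshold: float = 1.0,
                     pseudocount: float = LFC_PSEUDOCOUNT) -> PairwiseDEResults:
        """NB Wald test of group B vs group A on size-factor-normalized counts.

        The reported log2 fold-change is computed from normalized group
        means with a pseudocount; the p-value from the GLM group
        coefficient.  ``pass`` flags FDR <= ``fdr_threshold`` and
        |LFC| >= ``lfc_threshold``.
        """
        samples_a = self._samples(group_a)
        samples_b = self._samples(group_b)
        if len(samples_a) < 2 or len(samples_b) < 2:
            raise DesignError("each group needs >= 2 samples")
        if set(samples_a) & set(samples_b):
            raise DesignError("groups share samples; contrast is degenerate")
        col = {s: i for i, s in enumerate(self.counts.columns)}
        ia = np.array([col[s] for s in samples_a])
        ib = np.array([col[s] for s in samples_b])
        idx = np.concatenate([ia, ib])
        X = np.column_stack([np.ones(len(idx)),
                             np.r_[np.zeros(len(ia)), np.ones(len(ib))]])
        offset = np.log(self.size_factors.to_numpy()[idx])
        # dispersion from the replicate scatter of every design cell (the
        # two contrasted groups alone leave too few degrees of freedom),
        # moderated across genes
        alphas, ref_dof = self._dispersions()
        raw = self.counts.to_numpy()

        mean_a = self._group_means(ia)
        mean_b = self._group_means(ib)
        lfc = np.log2(mean_b + pseudocount) - np.log2(mean_a + pseudocount)

        n = raw.shape[0]
        pvals = np.ones(n)
        fallback = np.zeros(n, dtype=bool)
        low_info = np.zeros(n, dtype=bool)
        for g in range(n):
            y = raw[g, idx]
            if y.sum() == 0:
                low_info[g] = True
                continue
            res = _fit_glm(y, X, offset, alphas[g])
            if res is not None:
                z = res.params[1] / res.bse[1] if res.bse[1] > 0 else 0.0
                # Student reference with the moderated dispersion dof: a
                # plain normal reference is anticonservative with a noisy
                # plugin alpha at n = 3 per cell
                pvals[g] = 2 * scipy.stats.t.sf(abs(z), ref_dof)
            else:
                fallback[g] = True
                la = np.log2(self.norm[g, ia] + pseudocount)
                lb = np.log2(self.norm[g, ib] + pseudocount)
                if la.std(ddof=1) == 0 and lb.std(ddof=1) == 0:
                    pvals[g] = 1.0 if la.mean() == lb.mean() else 0.0
                else:
                    pvals[g] = scipy.stats.ttest_ind(
                        la, lb, equal_var=False).pvalue
        pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
        fdr = _bh(pvals)
        frame = pd.DataFrame({
            "lfc": lfc, "pvalue": pvals, "fdr": fdr,
            "pass": (fdr <= fdr_threshold) & (np.abs(lfc) >= lfc_threshold),
            "fallback": fallback, "low_information": low_info,
        }, index=self.counts.index)
        frame.loc[low_info, "pass"] = False
        return PairwiseDEResults(frame, samples_a, samples_b,
                                 fdr_threshold, lfc_threshold, pseudocount)

    # -- interaction LRT ---------------------------------------------------

    def _design_matrices(self):
        strains, treatments = self.strains, self.treatments
        if len(strains) < 2:
            raise DesignError("interaction needs both strains in the design")
        if len(treatments) < 2:
            raise DesignError("interaction needs >= 2 treatments")
        cell_counts = self.design.groupby(
            ["strain", "treatment"], observed=True).size()
        for s in strains:
            for t in treatments:
                if (s, t) not in cell_counts.index:
                    raise DesignError(
                        f"design cell strain={s}, treatment={t} is empty")
        strain_vec = self.design["strain"].to_numpy()
        treat_vec = self.design["treatment"].to_numpy()
        n = len(self.design)
        inter = np.ones((n, 1))
        strain_cols = [(strain_vec == s).astype(float)[:, None]
                       for s in strains[1:]]
        treat_cols = [(treat_vec == t).astype(float)[:, None]
                      for t in treatments[1:]]
        inter_cols = []
        for sc in strain_cols:
            for tc in treat_cols:
                inter_cols.append(sc * tc)
        X_reduced = np.hstack([inter] + strain_cols + treat_cols)
        X_full = np.hstack([X_reduced] + inter_cols)
        df = len(inter_cols)
        return X_full, X_reduced, df

    def fit_interaction(self, fdr_threshold: float = 0.05) -> InteractionResults:
        """Per-feature LRT of the strain:treatment interaction.

        The statistic is twice the log-likelihood gain of the full model
        over the reduced model with one degree of freedom per interaction
        column; the gene-wise dispersion is shared between the two fits.
        Because the dispersion is a noisy plugin estimate, stat/df is
        referred to F(df, dispersion dof) rather than the asymptotic
        chi-square — the standard quasi-likelihood small-sample reference.
        The direction label names the strain whose treatment response is
        larger, from the largest-magnitude fitted interaction coefficient.
        """
        X_full, X_reduced, df = self._design_matrices()
        raw = self.counts.to_numpy()
        offset = np.log(self.size_factors.to_numpy())
        alphas, ref_dof = self._dispersions()

        n = raw.shape[0]
        stat = np.zeros(n)
        pvals = np.ones(n)
        fallback = np.zeros(n, dtype=bool)
        direction = np.array([""] * n, dtype=object)
        n_inter = X_full.shape[1] - X_reduced.shape[1]
        for g in range(n):
            y = raw[g]
            if y.sum() == 0:
                fallback[g] = True
                continue
            res_f = _fit_glm(y, X_full, offset, alphas[g])
            res_r = _fit_glm(y, X_reduced, offset, alphas[g])
            if res_f is None or res_r is None:
                fallback[g] = True
                continue
            stat[g] = max(2.0 * (res_f.llf - res_r.llf), 0.0)
            # quasi-likelihood-style F reference: stat/df against
            # F(df, moderated dispersion dof); the asymptotic chi-square
            # reference is anticonservative with a raw plugin dispersion
            pvals[g] = scipy.stats.f.sf(stat[g] / df, df, ref_dof)
            coefs = res_f.params[-n_inter:]
            # coefficients measure strains[1]'s extra response relative to
            # strains[0]; the sign of the largest one labels the direction
            top = coefs[np.argmax(np.abs(coefs))]
            direction[g] = self.strains[1] if top > 0 else self.strains[0]
        pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
        fdr = _bh(pvals)
        frame = pd.DataFrame({
            "stat": stat, "df": df, "pvalue": pvals, "fdr": fdr,
            "direction": direction, "fallback": fallback,
        }, index=self.counts.index)
        return InteractionResults(frame, df, self.strains, self.treatments,
                                  fdr_threshold)

    # -- descriptive statistics -------------------------------------------

    def group_mean(self, group) -> pd.Series:
        samples = self._samples(group)
        col = {s: i for i, s in enumerate(self.counts.columns)}
        idx = np.array([col[s] for s in samples])
        return pd.Series(self._group_means(idx), index=self.counts.index)

    def fano_factor(self, condition: dict, features=None) -> pd.Series:
        """Variance/mean of normalized counts across a condition's replicates.

        Features with zero mean are undefined (NaN) and excluded from
        summaries.
        """
        samples = self._samples(condition)
        if len(samples) < 2:
            raise DesignError("Fano factor needs >= 2 replicate samples")
        col = {s: i for i, s in enumerate(self.counts.columns)}
        idx = np.array([col[s] for s in samples])
        sub = self.norm[:, idx]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            fano = np.where(m > 0, v / np.where(m > 0, m, 1.0), np.nan)
        out = pd.Series(fano, index=self.counts.index, name="fano")
        if features is not None:
            out = out.loc[features]
        return out

    def synergy_scores(self, strain, pseudocount: float = LFC_PSEUDOCOUNT,
                       fdr_threshold: float = 0.05,
                       lfc_threshold: float = 1.0) -> pd.DataFrame:
        """Per-gene synergy of the combined treatment within one strain.

        S = log2FC(IL4+LPS vs Ctrl) - log2FC(IL4 vs Ctrl) - log2FC(LPS vs
        Ctrl) on normalized means with a pseudocount.  The synergy flag
        requires S > 0 and a passing pairwise test of IL4+LPS against LPS.
        """
        present = set(self.design.loc[self.design["strain"] == strain,
                                      "treatment"])
        for t in ("Ctrl", "IL4", "LPS", "IL4+LPS"):
            if t not in present:
                raise DesignError(f"strain {strain} lacks treatment {t}")
        means = {t: self.group_mean({"strain": strain, "treatment": t})
                 for t in ("Ctrl", "IL4", "LPS", "IL4+LPS")}
        lfc = {t: np.log2(means[t] + pseudocount)
               - np.log2(means["Ctrl"] + pseudocount)
               for t in ("IL4", "LPS", "IL4+LPS")}
        score = lfc["IL4+LPS"] - lfc["IL4"] - lfc["LPS"]
        de = self.fit_pairwise({"strain": strain, "treatment": "LPS"},
                               {"strain": strain, "treatment": "IL4+LPS"},
                               fdr_threshold, lfc_threshold, pseudocount)
        flag = (score > 0) & de.frame["pass"] & (de.frame["lfc"] > 0)
        return pd.DataFrame({"score": score, "synergy": flag,
                             "combo_vs_lps_fdr": de.frame["fdr"],
                             "combo_vs_lps_lfc": de.frame["lfc"]})


# ---------------------------------------------------------------------------
# k-means on fold-change profiles (correlation distance)
# ---------------------------------------------------------------------------

def _standardize_rows(x: np.ndarray) -> np.ndarray:
    c = x - x.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(c, axis=1, keepdims=True)
    return c / norm


def kmeans_profiles(lfc_matrix: pd.DataFrame, k: int, n_restarts: int = 5,
                    seed: int = 0, max_iter: int = 300) -> ClusterResult:
    """Lloyd k-means under d(x, c) = 1 - Pearson(x, c), best of restarts.

    Rows with zero variance have no defined correlation and are dropped
    (reported in ``dropped``).  Restart-objective ties go to the lowest
    restart index; an emptied cluster is re-seeded to the farthest row.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    values = lfc_matrix.to_numpy(dtype=float)
    variable = values.std(axis=1) > 0
    dropped = list(lfc_matrix.index[~variable])
    data = values[variable]
    ids = lfc_matrix.index[variable]
    if len(data) == 0:
        raise ValueError("no rows with nonzero variance")
    if k > len(data):
        raise ValueError(f"k={k} exceeds usable rows ({len(data)})")
    z = _standardize_rows(data)
    rng = np.random.default_rng(seed)
    best = None
    for restart in range(n_restarts):
        centers = z[rng.choice(len(z), size=k, replace=False)].copy()
        labels = np.zeros(len(z), dtype=int)
        for _ in range(max_iter):
            sims = z @ centers.T
            new_labels = np.argmax(sims, axis=1)
            dist = 1.0 - sims[np.arange(len(z)), new_labels]
            for c in range(k):
                if not (new_labels == c).any():
                    far = np.argmax(dist)
                    new_labels[far] = c
                    dist[far] = 0.0
            if (new_labels == labels).all() and _ > 0:
                break
            labels = new_labels
            for c in range(k):
                members = z[labels == c]
                centers[c] = _standardize_rows(members.mean(axis=0)[None, :])[0]
        sims = z @ centers.T
        obj = float(np.sum(1.0 - sims[np.arange(len(z)), labels]))
        if best is None or obj < best[0] - 1e-12:
            best = (obj, labels.copy(), centers.copy())
    obj, labels, centers = best
    return ClusterResult(pd.Series(labels + 1, index=ids, name="cluster"),
                         centers, obj, dropped)


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def pairwise_de(counts, design, group_a, group_b, fdr_threshold=0.05,
                lfc_threshold=1.0, size_factors=None) -> PairwiseDEResults:
    model = StrainResponseModel(counts, design, size_factors)
    return model.fit_pairwise(group_a, group_b, fdr_threshold, lfc_threshold)


def interaction_lrt(counts, design, fdr_threshold=0.05,
                    size_factors=None) -> InteractionResults:
    model = StrainResponseModel(counts, design, size_factors)
    return model.fit_interaction(fdr_threshold)


def fano_factor(counts, design, condition: dict, features=None,
                size_factors=None) -> pd.Series:
    model = StrainResponseModel(counts, design, size_factors)
    return model.fano_factor(condition, features)


def synergy_score(counts, design, strain, size_factors=None) -> pd.DataFrame:
    model = StrainResponseModel(counts, design, size_factors)
    return model.synergy_scores(strain)
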
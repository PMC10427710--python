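"""Reference label transfer and cell-type-restricted expression imputation.

Spatial (panel-limited) cells and a dissociated reference share a
low-dimensional co-embedding (d = 15 by default); the co-embedding itself is
an input, not computed here.  Subtype labels move from reference to spatial
cells via a multi-class maximum-margin classifier trained on reference
latents: each query cell is represented by the mean latent of its k nearest
reference neighbors (k = 3) and assigned the label of maximum classification
probability.  Full-transcriptome expression is then imputed per query cell
as a convex combination of reference-cell expression restricted to the same
cell type — either Gaussian-kernel weights on latent distance (default) or
weights optimized on the probability simplex to maximize the mean per-gene
Pearson correlation with the measured panel.  Imputation fidelity is scored
by per-gene Pearson correlation across cells on shared genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "ReferenceSet",
    "LabelTransferClassifier",
    "ExpressionImputer",
    "ImputationResult",
    "annotate_major_types",
    "train_reference_classifier",
    "transfer_labels",
    "impute_expression",
    "evaluate_imputation",
]


@dataclass
class ReferenceSet:
    """Dissociated reference: counts, subtype labels, and shared latents."""

    cell_ids: list[str]
    counts: sparse.spmatrix  # cells x genes
    genes: list[str]
    labels: np.ndarray  # subtype per cell
    major_type: np.ndarray
    latents: np.ndarray  # cells x d

    def __post_init__(self) -> None:
        n = len(self.cell_ids)
        if not (
            self.counts.shape[0] == n
            and len(self.labels) == n
            and len(self.major_type) == n
            and self.latents.shape[0] == n
        ):
            raise ValueError("reference components are not indexed by the same cells")
        if self.counts.shape[1] != len(self.genes):
            raise ValueError("counts/genes dimension mismatch")
        if any(not lab for lab in self.labels):
            raise ValueError("every reference cell must carry a non-empty label")
        if not np.isfinite(self.latents).all():
            raise ValueError("latents must be finite")

    @property
    def latent_dim(self) -> int:
        return self.latents.shape[1]


def annotate_major_types(
    counts: sparse.spmatrix | np.ndarray,
    genes: list[str],
    marker_sets: dict[str, list[str]],
) -> np.ndarray:
    """Score-based major-type call per cell.

    ``score(type)`` is the mean over the type's markers of library-size
    normalized, per-gene z-scored expression; a cell gets the argmax type.
    All-zero cells and exact score ties are labeled ``"unassigned"``.
    Markers absent from the gene universe are skipped with a warning.
    """
    if not marker_sets or any(len(v) == 0 for v in marker_sets.values()):
        raise ValueError("each marker set must be non-empty")
    x = counts.toarray() if sparse.issparse(counts) else np.asarray(counts, float)
    gene_pos = {g: i for i, g in enumerate(genes)}
    totals = x.sum(axis=1)
    nonzero = totals > 0
    norm = np.zeros_like(x, dtype=float)
    norm[nonzero] = x[nonzero] / totals[nonzero, None]
    mu = norm.mean(axis=0)
    sd = norm.std(axis=0)
    sd[sd == 0] = 1.0
    z = (norm - mu) / sd

    types = sorted(marker_sets)
    scores = np.full((x.shape[0], len(types)), -np.inf)
    for t_i, t in enumerate(types):
        idx = []
        for g in marker_sets[t]:
            if g not in gene_pos:
                warnings.warn(f"marker gene {g!r} absent; skipped", stacklevel=2)
                continue
            idx.append(gene_pos[g])
        if not idx:
            raise ValueError(f"no marker of type {t!r} present in the gene universe")
        scores[:, t_i] = z[:, idx].mean(axis=1)
    best = np.argmax(scores, axis=1)
    top = scores[np.arange(len(best)), best]
    ties = (scores == top[:, None]).sum(axis=1) > 1
    out = np.array([types[b] for b in best], dtype=object)
    out[~nonzero | ties] = "unassigned"
    return out


class LabelTransferClassifier(BaseEstimator, ClassifierMixin):
    """Multi-class maximum-margin label transfer over co-embedding latents.

    A linear-kernel SVM with pairwise-coupling probability calibration,
    seed-fixed for deterministic training.  ``predict`` on raw query latents
    classifies them directly; :meth:`transfer` implements the
    neighbor-averaged scheme (the query feature is the mean latent of its
    ``k`` nearest reference cells).

    Parameters
    ----------
    C : SVM regularization strength.
    k : default number of reference neighbors for :meth:`transfer`.
    random_state : seed for the probability-calibration fold split.
    """

    def __init__(self, C: float = 1.0, k: int = 3, random_state: int = 0):
        self.C = C
        self.k = k
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("need at least two classes to train a classifier")
        if counts.min() < 2:
            small = classes[counts < 2].tolist()
            raise ValueError(f"classes with fewer than 2 cells: {small}")
        self.svm_ = SVC(
            kernel="linear",
            C=self.C,
            probability=True,
            random_state=self.random_state,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            self.svm_.fit(X, y)
        self.classes_ = self.svm_.classes_
        self.ref_latents_ = X
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "svm_")
        return self.svm_.predict_proba(np.asarray(X, dtype=float))

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]

    def transfer(
        self, query_latents: np.ndarray, k: int | None = None
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Neighbor-averaged classification of query latents.

        Returns ``(labels, probabilities, neighbor_indices)``.
        """
        check_is_fitted(self, "svm_")
        k = self.k if k is None else int(k)
        if k < 1:
            raise ValueError("k must be >= 1")
        if k > len(self.ref_latents_):
            raise ValueError("k exceeds the number of reference cells")
        q = np.asarray(query_latents, dtype=float)
        if q.shape[1] != self.n_features_in_:
            raise ValueError("query latent dimension differs from the reference")
        tree = cKDTree(self.ref_latents_)
        _, nbr = tree.query(q, k=k)
        nbr = nbr.reshape(len(q), k)
        feats = self.ref_latents_[nbr].mean(axis=1)
        proba = self.predict_proba(feats)
        labels = self.classes_[np.argmax(proba, axis=1)]
        return labels, proba, nbr


def train_reference_classifier(
    ref: ReferenceSet, C: float = 1.0, seed: int = 0
) -> LabelTransferClassifier:
    """Fit the label-transfer classifier on reference latents and labels."""
    clf = LabelTransferClassifier(C=C, random_state=seed)
    return clf.fit(ref.latents, ref.labels)


def transfer_labels(
    query_latents: np.ndarray,
    ref: ReferenceSet,
    classifier: LabelTransferClassifier | None = None,
    k: int = 3,
    query_ids: list[str] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Assign reference labels to query cells through the latent space.

    Returns one row per query cell: assigned label, its probability, the
    reference neighbor ids used, and per-class probability columns.
    """
    clf = classifier or train_reference_classifier(ref, seed=seed)
    labels, proba, nbr = clf.transfer(query_latents, k=k)
    ids = query_ids if query_ids is not None else [f"q{i}" for i in range(len(labels))]
    ref_ids = np.asarray(ref.cell_ids, dtype=object)
    out = pd.DataFrame(
        {
            "cell_id": ids,
            "assigned_label": labels,
            "probability": proba.max(axis=1),
            "neighbor_ids": [";".join(ref_ids[row]) for row in nbr],
        }
    )
    for j, cls in enumerate(clf.classes_):
        out[f"prob_{cls}"] = proba[:, j]
    return out


@dataclass
class ImputationResult:
    """Imputed expression plus the audit trail of the weights used."""

    imputed: np.ndarray  # query cells x genes (NaN rows for flagged cells)
    genes: list[str]
    flagged: list[str] = field(default_factory=list)  # query ids with no same-type reference
    weights: sparse.csr_matrix | None = None  # query cells x reference cells
    mean_panel_pcc: float | None = None


class ExpressionImputer(BaseEstimator):
    """Same-cell-type kNN imputation of full-transcriptome expression.

    For each query cell the candidate pool is its ``k`` nearest reference
    cells *of the same type* in latent space; the imputed profile is the
    weighted sum of their expression.  ``mode="kernel"`` uses a Gaussian
    kernel on latent distance with bandwidth equal to the median candidate
    distance of that cell.  ``mode="fit"`` starts from the kernel weights and
    optimizes them on the simplex (softmax parameterization, projected
    gradient ascent) to maximize the mean per-gene Pearson correlation
    between imputed and measured panel genes; the best iterate is kept, so
    the fit never scores below the kernel start.

    Parameters
    ----------
    k : neighbors per query cell (default 30).
    mode : ``"kernel"`` or ``"fit"``.
    max_iter, tol : fit-mode iteration cap and relative-improvement tolerance.
    """

    def __init__(
        self,
        k: int = 30,
        mode: str = "kernel",
        max_iter: int = 60,
        tol: float = 1e-6,
        step: float = 1.0,
    ):
        self.k = k
        self.mode = mode
        self.max_iter = max_iter
        self.tol = tol
        self.step = step

    def fit(self, ref: ReferenceSet, ref_types: np.ndarray | None = None):
        """Index the reference; ``ref_types`` defaults to major types."""
        if self.mode not in ("kernel", "fit"):
            raise ValueError("mode must be 'kernel' or 'fit'")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        self.ref_ = ref
        self.ref_types_ = np.asarray(
            ref.major_type if ref_types is None else ref_types, dtype=object
        )
        self.ref_expr_ = (
            ref.counts.toarray().astype(float)
            if sparse.issparse(ref.counts)
            else np.asarray(ref.counts, dtype=float)
        )
        self.trees_ = {}
        self.type_index_ = {}
        for t in np.unique(self.ref_types_):
            idx = np.flatnonzero(self.ref_types_ == t)
            self.type_index_[t] = idx
            self.trees_[t] = cKDTree(ref.latents[idx])
        return self

    def transform(
        self,
        query_latents: np.ndarray,
        query_types: np.ndarray,
        query_ids: list[str] | None = None,
        measured: np.ndarray | sparse.spmatrix | None = None,
        panel: list[str] | None = None,
    ) -> ImputationResult:
        check_is_fitted(self, "ref_")
        q = np.asarray(query_latents, dtype=float)
        qt = np.asarray(query_types, dtype=object)
        if len(q) != len(qt):
            raise ValueError("query latents and types length mismatch")
        ids = query_ids if query_ids is not None else [f"q{i}" for i in range(len(q))]
        n_ref = len(self.ref_.cell_ids)
        n_genes = len(self.ref_.genes)
        imputed = np.full((len(q), n_genes), np.nan)
        w_rows: list[int] = []
        w_cols: list[int] = []
        w_vals: list[float] = []
        flagged: list[str] = []
        cand_of: dict[int, np.ndarray] = {}
        weight_of: dict[int, np.ndarray] = {}
        for qi in range(len(q)):
            t = qt[qi]
            if t not in self.trees_:
                flagged.append(ids[qi])
                continue
            pool = self.type_index_[t]
            kk = min(self.k, len(pool))
            dist, loc = self.trees_[t].query(q[qi], k=kk)
            dist, loc = np.atleast_1d(dist), np.atleast_1d(loc)
            cand = pool[loc]
            h = np.median(dist)
            if h <= 0:
                w = (dist <= 0).astype(float)
            else:
                w = np.exp(-0.5 * (dist / h) ** 2)
            w = w / w.sum()
            cand_of[qi] = cand
            weight_of[qi] = w

        if self.mode == "fit":
            if measured is None or panel is None:
                raise ValueError("fit mode requires measured panel expression")
            weight_of = self._fit_weights(q, cand_of, weight_of, measured, panel)

        for qi, cand in cand_of.items():
            w = weight_of[qi]
            imputed[qi] = w @ self.ref_expr_[cand]
            w_rows += [qi] * len(cand)
            w_cols += cand.tolist()
            w_vals += w.tolist()
        weights = sparse.csr_matrix(
            (w_vals, (w_rows, w_cols)), shape=(len(q), n_ref)
        )
        # audit: convexity and type purity on every run
        sums = np.asarray(weights.sum(axis=1)).ravel()
        ok_rows = np.array([qi in cand_of for qi in range(len(q))])
        if not np.allclose(sums[ok_rows], 1.0, atol=1e-8):
            raise AssertionError("imputation weights do not sum to 1")
        coo = weights.tocoo()
        if len(coo.data) and (self.ref_types_[coo.col] != qt[coo.row]).any():
            raise AssertionError("imputation weight crosses the type restriction")

        mean_pcc = None
        if measured is not None and panel is not None and ok_rows.any():
            mean_pcc = self._mean_panel_pcc(imputed[ok_rows], measured, panel, ok_rows)
        return ImputationResult(
            imputed=imputed,
            genes=list(self.ref_.genes),
            flagged=flagged,
            weights=weights,
            mean_panel_pcc=mean_pcc,
        )

    # -- fit mode ---------------------------------------------------------

    def _panel_arrays(self, measured, panel):
        m = measured.toarray() if sparse.issparse(measured) else np.asarray(measured, float)
        if m.shape[1] != len(panel):
            raise ValueError("measured matrix must have one column per panel gene")
        pos = {g: i for i, g in enumerate(self.ref_.genes)}
        keep = [i for i, g in enumerate(panel) if g in pos]
        if not keep:
            raise ValueError("no panel gene present in the reference gene set")
        panel_idx = np.array([pos[panel[i]] for i in keep], dtype=int)
        meas_panel = m[:, keep]
        return meas_panel, panel_idx

    def _mean_panel_pcc(self, imputed_ok, measured, panel, ok_rows) -> float:
        meas_panel, panel_idx = self._panel_arrays(measured, panel)
        meas_ok = meas_panel[ok_rows]
        pcc = _pergene_pcc(imputed_ok[:, panel_idx], meas_ok)
        return float(np.nanmean(pcc))

    def _fit_weights(self, q, cand_of, weight_of, measured, panel):
        meas_panel, panel_idx = self._panel_arrays(measured, panel)
        rows = sorted(cand_of)
        k_max = max(len(cand_of[r]) for r in rows)
        E = np.zeros((len(rows), k_max, len(panel_idx)))
        mask = np.zeros((len(rows), k_max), dtype=bool)
        for r_i, qi in enumerate(rows):
            cand = cand_of[qi]
            E[r_i, : len(cand)] = self.ref_expr_[np.ix_(cand, panel_idx)]
            mask[r_i, : len(cand)] = True
        Y = meas_panel[rows]
        W0 = np.zeros((len(rows), k_max))
        for r_i, qi in enumerate(rows):
            W0[r_i, : len(cand_of[qi])] = weight_of[qi]

        def objective(W):
            X = np.einsum("rk,rkg->rg", W, E)
            return np.nanmean(_pergene_pcc(X, Y)), X

        def grad(W, X):
            n = X.shape[0]
            Xc = X - X.mean(axis=0)
            Yc = Y - Y.mean(axis=0)
            sx = np.sqrt((Xc ** 2).sum(axis=0))
            sy = np.sqrt((Yc ** 2).sum(axis=0))
            valid = (sx > 0) & (sy > 0)
            g_x = np.zeros_like(X)
            r = np.zeros(X.shape[1])
            r[valid] = (Xc[:, valid] * Yc[:, valid]).sum(axis=0) / (
                sx[valid] * sy[valid]
            )
            g_x[:, valid] = (
                Yc[:, valid] / (sx[valid] * sy[valid])
                - Xc[:, valid] * (r[valid] / sx[valid] ** 2)
            )
            g_x /= max(valid.sum(), 1)
            return np.einsum("rg,rkg->rk", g_x, E)

        # softmax parameterization keeps weights on the simplex
        logits = np.log(np.clip(W0, 1e-12, None))
        logits[~mask] = -np.inf
        best_obj, _ = objective(W0)
        best_W = W0.copy()
        obj_prev = best_obj
        step = self.step
        for _ in range(self.max_iter):
            W = _masked_softmax(logits, mask)
            obj, X = objective(W)
            if obj > best_obj:
                best_obj, best_W = obj, W.copy()
            g_w = grad(W, X)
            g_logits = W * (g_w - (g_w * W).sum(axis=1, keepdims=True))
            g_logits[~mask] = 0.0
            logits = np.where(mask, logits + step * g_logits, logits)
            if abs(obj - obj_prev) < self.tol * max(abs(obj_prev), 1e-12):
                break
            obj_prev = obj
        W_final = _masked_softmax(logits, mask)
        obj_final, _ = objective(W_final)
        if obj_final > best_obj:
            best_obj, best_W = obj_final, W_final
        return {
            qi: best_W[r_i, : len(cand_of[qi])] / best_W[r_i, : len(cand_of[qi])].sum()
            for r_i, qi in enumerate(sorted(cand_of))
        }


def _masked_softmax(logits: np.ndarray, mask: np.ndarray) -> np.ndarray:
    z = np.where(mask, logits, -np.inf)
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    e[~mask] = 0.0
    return e / e.sum(axis=1, keepdims=True)


def impute_expression(
    query_latents: np.ndarray,
    query_types: np.ndarray,
    ref: ReferenceSet,
    mode: str = "kernel",
    k: int = 30,
    restrict: str = "major",
    measured=None,
    panel: list[str] | None = None,
    query_ids: list[str] | None = None,
) -> ImputationResult:
    """Impute full-transcriptome expression for query cells.

    ``restrict`` chooses the type restriction level: ``"major"`` matches
    query major types against reference major types; ``"subtype"`` restricts
    within subtype labels (query_types must then be subtype labels).
    """
    if restrict not in ("major", "subtype"):
        raise ValueError("restrict must be 'major' or 'subtype'")
    ref_types = ref.major_type if restrict == "major" else ref.labels
    imp = ExpressionImputer(k=k, mode=mode).fit(ref, ref_types=ref_types)
    return imp.transform(
        query_latents, query_types, query_ids=query_ids, measured=measured, panel=panel
    )


def _pergene_pcc(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation per column (gene) across rows (cells); NaN for
    zero-variance columns."""
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    sx = np.sqrt((xc ** 2).sum(axis=0))
    sy = np.sqrt((yc ** 2).sum(axis=0))
    out = np.full(x.shape[1], np.nan)
    valid = (sx > 0) & (sy > 0)
    out[valid] = (xc[:, valid] * yc[:, valid]).sum(axis=0) / (sx[valid] * sy[valid])
    return out


def evaluate_imputation(
    imputed: np.ndarray,
    measured: np.ndarray | sparse.spmatrix,
    genes: list[str],
    measured_genes: list[str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-gene Pearson correlation between imputed and measured expression.

    ``genes`` names the columns of ``imputed``; ``measured_genes`` (default:
    same) names the columns of ``measured``.  Only shared genes are scored.
    Zero-variance genes are reported with NaN and excluded from the summary.
    """
    m = measured.toarray() if sparse.issparse(measured) else np.asarray(measured, float)
    measured_genes = genes if measured_genes is None else measured_genes
    shared = [g for g in genes if g in set(measured_genes)]
    if not shared:
        raise ValueError("no shared genes between imputed and measured")
    gi = {g: i for i, g in enumerate(genes)}
    mi = {g: i for i, g in enumerate(measured_genes)}
    xi = np.asarray(imputed)[:, [gi[g] for g in shared]]
    yi = m[:, [mi[g] for g in shared]]
    keep = ~np.isnan(xi).any(axis=1)
    pcc = _pergene_pcc(xi[keep], yi[keep])
    table = pd.DataFrame({"gene": shared, "pcc": pcc})
    defined = table["pcc"].dropna()
    summary = {
        "median_pcc": float(defined.median()) if len(defined) else np.nan,
        "mean_pcc": float(defined.mean()) if len(defined) else np.nan,
        "n_genes": int(len(defined)),
        "n_undefined": int(table["pcc"].isna().sum()),
    }
    return table, summary
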
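"""Linear-discriminant label transfer with a rejection option.

A homoscedastic Gaussian classifier (class means, pooled within-class
covariance, empirical priors) trained on labeled intestinal cells maps
new cells - a held-out cohort, or blood cells - onto the training
subsets. Posteriors are computed in log space (log-sum-exp); a cell is
assigned to the argmax class only when its maximum posterior reaches
the rejection threshold tau, otherwise it is labeled REJECTED. tau = 1
is interpreted as posterior >= 1 - 1e-6: floating-point saturation makes
an exact 1.0 attainable but brittle, and the epsilon preserves the
"100% confidence" semantics deterministically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve

from .data import REJECTED, CellTable, FrequencyMatrix
from .preprocess import compute_frequencies

#: numerical slack on the rejection threshold (tau = 1 means >= 1 - EPS).
EPS_NUM = 1e-6


@dataclass
class LDAModel:
    classes: list[str]
    means: np.ndarray          # (K, d)
    covariance: np.ndarray     # (d, d), pooled within-class + ridge
    priors: np.ndarray         # (K,), sums to 1
    markers: list[str]

    def __post_init__(self) -> None:
        if not np.allclose(self.priors.sum(), 1.0):
            raise ValueError("priors must sum to 1")
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-8):
            raise ValueError("covariance must be symmetric")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "classes": self.classes,
            "means": self.means.tolist(),
            "covariance": self.covariance.tolist(),
            "priors": self.priors.tolist(),
            "markers": self.markers,
        }))

    @classmethod
    def from_json(cls, path: str | Path) -> "LDAModel":
        d = json.loads(Path(path).read_text())
        return cls(
            classes=d["classes"], means=np.array(d["means"]),
            covariance=np.array(d["covariance"]),
            priors=np.array(d["priors"]), markers=d["markers"],
        )


def fit_lda(
    cells: CellTable,
    labels: np.ndarray,
    reg: float | None = None,
) -> LDAModel:
    """Pooled-covariance LDA fit.

    Sigma = sum of class scatter / (N - K) + reg * I; ``reg`` defaults to
    1e-6 times the mean pooled variance. Requires >= 2 classes with at
    least n_markers + 1 cells each.
    """
    labels = np.asarray(labels)
    classes = sorted(pd.unique(labels))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    x = cells.values.astype(np.float64)
    n, d = x.shape
    means, scatter, priors = [], np.zeros((d, d)), []
    for c in classes:
        xc = x[labels == c]
        if len(xc) < d + 1:
            raise ValueError(
                f"class {c!r} has {len(xc)} cells; need at least {d + 1}")
        mu = xc.mean(axis=0)
        means.append(mu)
        dev = xc - mu
        scatter += dev.T @ dev
        priors.append(len(xc) / n)
    cov = scatter / (n - len(classes))
    if reg is None:
        mean_diag = float(np.mean(np.diag(cov)))
        # absolute floor covers degenerate (point-mass) classes
        reg = 1e-6 * (mean_diag if mean_diag > 0 else 1.0)
    cov = cov + reg * np.eye(d)
    # fail early on a degenerate covariance
    try:
        cho_factor(cov)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "pooled covariance singular after regularization") from exc
    return LDAModel(
        classes=list(classes), means=np.stack(means),
        covariance=cov, priors=np.array(priors), markers=list(cells.markers),
    )


@dataclass
class TransferResult:
    """Per-cell predictions plus the derived per-sample frequencies."""

    labels: np.ndarray          # predicted subset or REJECTED
    max_posterior: np.ndarray
    tau: float
    sample_id: np.ndarray
    matched_fraction: float
    #: denominator convention of pred_freq: "assigned" excludes rejected
    #: cells, "all" keeps every gated cell in the denominator.
    denominator: str = "assigned"
    pred_freq: FrequencyMatrix | None = None


def _log_posteriors(model: LDAModel, x: np.ndarray) -> np.ndarray:
    factor = cho_factor(model.covariance)
    # squared Mahalanobis distance of every cell to every class mean
    maha = np.empty((x.shape[0], len(model.classes)))
    for k, mu in enumerate(model.means):
        dev = x - mu
        maha[:, k] = np.einsum("ij,ij->i", dev, cho_solve(factor, dev.T).T)
    logp = np.log(model.priors)[None, :] - 0.5 * maha
    logp -= logp.max(axis=1, keepdims=True)
    logz = np.log(np.exp(logp).sum(axis=1, keepdims=True))
    return logp - logz


def posterior_matrix(model: LDAModel, cells: CellTable) -> np.ndarray:
    """Class posteriors per cell (rows sum to 1)."""
    x = _align(model, cells)
    return np.exp(_log_posteriors(model, x))


def _align(model: LDAModel, cells: CellTable) -> np.ndarray:
    """Restrict cells to the model's marker channels, in model order."""
    missing = set(model.markers) - set(cells.markers)
    if missing:
        raise ValueError(f"cells lack model markers {sorted(missing)}")
    idx = [cells.markers.index(m) for m in model.markers]
    return cells.values[:, idx].astype(np.float64)


def predict_with_rejection(
    model: LDAModel,
    cells: CellTable,
    tau: float,
    batch: int = 100_000,
) -> TransferResult:
    """Assign argmax class where max posterior >= tau - 1e-6, else reject."""
    if not 0 < tau <= 1:
        raise ValueError("tau must lie in (0, 1]")
    x = _align(model, cells)
    labels = np.empty(len(x), dtype=object)
    maxpost = np.empty(len(x))
    classes = np.array(model.classes, dtype=object)
    for start in range(0, len(x), batch):
        post = np.exp(_log_posteriors(model, x[start:start + batch]))
        arg = post.argmax(axis=1)
        mp = post[np.arange(len(post)), arg]
        lab = classes[arg]
        lab[mp < tau - EPS_NUM] = REJECTED
        labels[start:start + len(post)] = lab
        maxpost[start:start + len(post)] = mp
    matched = float((labels != REJECTED).mean()) if len(labels) else 0.0
    return TransferResult(
        labels=labels.astype(str), max_posterior=maxpost, tau=tau,
        sample_id=cells.sample_id, matched_fraction=matched,
    )


def predicted_frequencies(
    result: TransferResult,
    metadata: pd.DataFrame | None = None,
    mode: str = "total_CD45",
    all_subsets: list[str] | None = None,
    denominator: str = "assigned",
) -> FrequencyMatrix:
    """Frequency matrix over predicted labels.

    ``denominator="assigned"`` divides by non-rejected cells only (the
    compute_frequencies convention); ``"all"`` divides by every cell,
    which is the convention for blood-matching fractions.
    """
    freq = compute_frequencies(
        result.labels, result.sample_id, metadata=metadata, mode=mode,
        all_subsets=all_subsets,
    )
    if denominator == "all":
        totals = pd.Series(result.sample_id).value_counts()
        assigned = pd.Series(result.sample_id[result.labels != REJECTED]
                             ).value_counts().reindex(totals.index, fill_value=0)
        scale = (assigned / totals).reindex(freq.samples).to_numpy()
        freq = FrequencyMatrix(
            values=freq.values.mul(scale, axis=0), mode=freq.mode,
            metadata=freq.metadata)
    elif denominator != "assigned":
        raise ValueError("denominator must be 'assigned' or 'all'")
    result.pred_freq = freq
    result.denominator = denominator
    return freq


def frequency_concordance(
    true_freq: FrequencyMatrix | pd.DataFrame,
    pred_freq: FrequencyMatrix | pd.DataFrame,
    per_subset: bool = False,
):
    """Pearson R between true and predicted frequencies.

    Default pools all (sample, subset) entries into one flattened pair of
    vectors; ``per_subset`` returns one R per subset column instead.
    """
    t = true_freq.values if isinstance(true_freq, FrequencyMatrix) else true_freq
    p = pred_freq.values if isinstance(pred_freq, FrequencyMatrix) else pred_freq
    common_s = t.index.intersection(p.index)
    common_k = t.columns.intersection(p.columns)
    if len(common_s) == 0 or len(common_k) == 0:
        raise ValueError("matrices share no samples/subsets")
    t = t.loc[common_s, common_k].to_numpy(dtype=float)
    p = p.loc[common_s, common_k].to_numpy(dtype=float)
    if per_subset:
        return pd.Series(
            [stats.pearsonr(t[:, j], p[:, j]).statistic
             for j in range(t.shape[1])], index=common_k)
    tf, pf = t.ravel(), p.ravel()
    if tf.std() == 0 or pf.std() == 0:
        raise ValueError("zero variance in flattened frequencies")
    return float(stats.pearsonr(tf, pf).statistic)


def mahalanobis_outliers(
    model: LDAModel, cells: CellTable, quantile: float = 0.999
) -> np.ndarray:
    """True for cells farther than the chi-square cut from every class.

    Posteriors always normalize over the known classes, so a cell far
    from all of them can still get a confident assignment; this flag
    provides genuine novelty rejection.
    """
    x = _align(model, cells)
    factor = cho_factor(model.covariance)
    cut = stats.chi2.ppf(quantile, df=x.shape[1])
    best = np.full(len(x), np.inf)
    for mu in model.means:
        dev = x - mu
        maha = np.einsum("ij,ij->i", dev, cho_solve(factor, dev.T).T)
        best = np.minimum(best, maha)
    return best > cut


def match_blood_to_tissue(
    model: LDAModel,
    blood_cells: CellTable,
    tau: float = 1.0,
    metadata: pd.DataFrame | None = None,
    all_subsets: list[str] | None = None,
) -> tuple[TransferResult, pd.Series]:
    """Match blood cells to intestinal phenotypes under rejection.

    Returns the transfer result (with per-sample matched frequencies as
    percent of all blood CD45+ cells) and the per-subset matched
    fractions across all blood cells.
    """
    result = predict_with_rejection(model, blood_cells, tau)
    predicted_frequencies(
        result, metadata=metadata, all_subsets=all_subsets, denominator="all")
    assigned = result.labels[result.labels != REJECTED]
    per_subset = (
        pd.Series(assigned).value_counts() / max(len(result.labels), 1)
    ).reindex(all_subsets or model.classes, fill_value=0.0)
    per_subset.name = "matched_fraction"
    return result, per_subset
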
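"""Booleanization of expression measurements.

Two routes convert measurements into per-gene Boolean states plus expression
probabilities:

* the barcode mixture route — each gene's normalized log2 value is scored
  under a two-component mixture: a Gaussian N(mu, sigma) of non-expressed
  values and a Uniform(mu, upper) of expressed values (upper defaults to 15);
  a gene is called expressed when its probability of belonging to the
  expressed component exceeds a cutoff (default 0.95, strict);
* the detection-call route — probability = 1 - p for a detection-call
  p-value, expressed when probability >= threshold (default 0.94, inclusive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from signalflip.errors import InputError, ParameterError

logger = logging.getLogger(__name__)

DEFAULT_UPPER = 15.0
BARCODE_CUTOFF = 0.95
DETECTION_THRESHOLD = 0.94


@dataclass
class BarcodeParams:
    """Per-gene parameters of the non-expressed Gaussian component.

    ``mu``/``sigma`` index by gene id; ``upper`` is the shared upper bound of
    the expressed Uniform component, in the same log2 units.
    """

    mu: "pd.Series"
    sigma: "pd.Series"
    upper: float = DEFAULT_UPPER

    def __post_init__(self) -> None:
        self.mu = pd.Series(self.mu, dtype=float)
        self.sigma = pd.Series(self.sigma, dtype=float)
        if not self.mu.index.equals(self.sigma.index):
            self.sigma = self.sigma.reindex(self.mu.index)
        if (self.sigma <= 0).any():
            bad = list(self.sigma.index[self.sigma <= 0])
            raise ParameterError(f"sigma must be > 0; offending genes: {bad[:5]}")
        if (self.mu >= self.upper).any():
            bad = list(self.mu.index[self.mu >= self.upper])
            raise ParameterError(
                f"upper ({self.upper}) must exceed mu; offending genes: {bad[:5]}"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.mu.index)

    @classmethod
    def from_tsv(cls, path, upper: float = DEFAULT_UPPER) -> "BarcodeParams":
        """Read ``gene<TAB>mu<TAB>sigma`` with an optional header line."""
        df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype={0: str})
        if df.shape[1] != 3:
            raise InputError("barcode params TSV needs 3 columns: gene, mu, sigma")
        # tolerate a header row
        try:
            float(df.iloc[0, 1])
        except (TypeError, ValueError):
            df = df.iloc[1:]
        df.columns = ["gene", "mu", "sigma"]
        df = df.set_index("gene")
        return cls(df["mu"].astype(float), df["sigma"].astype(float), upper=upper)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame({"mu": self.mu, "sigma": self.sigma})
        df.index.name = "gene"
        df.to_csv(path, sep="\t")


@dataclass
class BooleanTransition:
    """Boolean states and expression probabilities of the two cell states."""

    genes: list[str]
    state_initial: np.ndarray
    state_final: np.ndarray
    prob_initial: np.ndarray
    prob_final: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.genes)
        for name in ("state_initial", "state_final", "prob_initial", "prob_final"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n,):
                raise InputError(f"{name} must have length {n}, got {arr.shape}")
            setattr(self, name, arr)
        for name in ("state_initial", "state_final"):
            arr = getattr(self, name)
            if not np.isin(arr, (0, 1)).all():
                raise InputError(f"{name} must be 0/1")
            setattr(self, name, arr.astype(int))
        for name in ("prob_initial", "prob_final"):
            arr = getattr(self, name).astype(float)
            if ((arr < 0) | (arr > 1)).any():
                raise InputError(f"{name} must lie in [0, 1]")
            setattr(self, name, arr)
        self._index = {g: i for i, g in enumerate(self.genes)}

    def index_of(self, gene: str) -> int:
        return self._index[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def initial_state_of(self, gene: str) -> int:
        return int(self.state_initial[self._index[gene]])

    def final_state_of(self, gene: str) -> int:
        return int(self.state_final[self._index[gene]])

    def initial_prob_of(self, gene: str) -> float:
        return float(self.prob_initial[self._index[gene]])


def expression_probability(
    value: float, mu: float, sigma: float, upper: float = DEFAULT_UPPER
) -> float:
    """Probability that ``value`` belongs to the expressed mixture component.

    p = (0.5 * f_e) / (0.5 * f_e + 0.5 * f_n) where f_e is the Uniform(mu,
    upper) density and f_n the Normal(mu, sigma) density at ``value``.
    Returns 0 when both densities vanish.
    """
    if sigma <= 0:
        raise ParameterError(f"sigma must be > 0, got {sigma}")
    if upper <= mu:
        raise ParameterError(f"upper ({upper}) must exceed mu ({mu})")
    f_e = stats.uniform.pdf(value, loc=mu, scale=upper - mu)
    f_n = stats.norm.pdf(value, loc=mu, scale=sigma)
    denom = 0.5 * f_e + 0.5 * f_n
    if denom == 0.0:
        return 0.0
    return float(0.5 * f_e / denom)


def _probability_matrix(values: pd.DataFrame, params: BarcodeParams) -> pd.DataFrame:
    mu = params.mu.loc[values.index].to_numpy()[:, None]
    sigma = params.sigma.loc[values.index].to_numpy()[:, None]
    x = values.to_numpy(dtype=float)
    f_e = stats.uniform.pdf(x, loc=mu, scale=params.upper - mu)
    f_n = stats.norm.pdf(x, loc=mu, scale=sigma)
    denom = 0.5 * f_e + 0.5 * f_n
    with np.errstate(invalid="ignore"):
        p = np.where(denom > 0, 0.5 * f_e / np.where(denom > 0, denom, 1.0), 0.0)
    return pd.DataFrame(p, index=values.index, columns=values.columns)


def booleanize_barcode(
    values: pd.DataFrame,
    params: BarcodeParams,
    cutoff: float = BARCODE_CUTOFF,
) -> tuple[np.ndarray, np.ndarray]:
    """Booleanize a genes x replicates matrix under the barcode mixture.

    Per gene the probability is the maximum of :func:`expression_probability`
    across replicate columns; the state is 1 iff that probability is strictly
    greater than ``cutoff``. Missing values are treated as non-expressed
    (probability 0) and logged.

    Returns ``(states, probabilities)`` aligned with ``values.index``.
    """
    if not 0 < cutoff < 1:
        raise ParameterError(f"cutoff must lie in (0, 1), got {cutoff}")
    missing = [g for g in values.index if g not in params.mu.index]
    if missing:
        raise InputError(
            f"{len(missing)} gene(s) missing from barcode params: {missing[:10]}"
        )
    values = values.astype(float)
    n_missing = int(values.isna().to_numpy().sum())
    if n_missing:
        logger.warning("treating %d missing expression values as non-expressed", n_missing)
    probs_df = _probability_matrix(values, params)
    probs_df = probs_df.where(~values.isna(), 0.0)
    probs = probs_df.max(axis=1).fillna(0.0).to_numpy()
    states = (probs > cutoff).astype(int)
    return states, probs


def booleanize_detection_call(
    pvalues: pd.Series, threshold: float = DETECTION_THRESHOLD
) -> tuple[np.ndarray, np.ndarray]:
    """Booleanize detection-call p-values: probability = 1 - p, state at >= threshold."""
    p = pd.Series(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        bad = list(p.index[(p < 0) | (p > 1)])
        raise ParameterError(f"p-values must lie in [0, 1]; offending genes: {bad[:5]}")
    probs = (1.0 - p).to_numpy()
    states = (probs >= threshold).astype(int)
    return states, probs


def collapse_probes(
    values: pd.DataFrame, probe_to_gene: pd.Series
) -> pd.DataFrame:
    """Keep, per gene, the probe with the highest variance across all samples."""
    var = values.var(axis=1, ddof=1).fillna(0.0)
    df = values.copy()
    df["_gene"] = probe_to_gene.reindex(values.index)
    df["_var"] = var
    df = df.dropna(subset=["_gene"])
    best = df.sort_values("_var", ascending=False).groupby("_gene", sort=True).head(1)
    out = best.drop(columns=["_var"]).set_index("_gene")
    out.index.name = None
    return out.sort_index()


def build_transition(
    initial: tuple[np.ndarray, np.ndarray],
    final: tuple[np.ndarray, np.ndarray],
    genes_initial: list[str],
    genes_final: list[str] | None = None,
) -> BooleanTransition:
    """Assemble a :class:`BooleanTransition` over the shared gene set."""
    if genes_final is None:
        genes_final = genes_initial
    idx_i = {g: k for k, g in enumerate(genes_initial)}
    idx_f = {g: k for k, g in enumerate(genes_final)}
    common = [g for g in genes_initial if g in idx_f]
    if not common:
        raise InputError("initial and final gene sets are disjoint")
    si, pi = initial
    sf, pf = final
    rows_i = [idx_i[g] for g in common]
    rows_f = [idx_f[g] for g in common]
    return BooleanTransition(
        genes=common,
        state_initial=np.asarray(si)[rows_i],
        state_final=np.asarray(sf)[rows_f],
        prob_initial=np.asarray(pi)[rows_i],
        prob_final=np.asarray(pf)[rows_f],
    )


def read_expression_tsv(path) -> pd.DataFrame:
    """Read an expression matrix TSV (first column gene id, rest replicates)."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return df.astype(float)
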
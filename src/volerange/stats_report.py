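"""Exact tests, the PCA screening stage, and report assembly.

The enclosure design yields small counts, so inference is exact: a
two-tailed sign (binomial) test for resident-vs-wanderer imbalance and
Fisher's exact test for tactic x surgery independence. The PCA stage
screens the inter-dependency of the per-male space-use and reproductive
features on the correlation matrix, reporting loadings with magnitude
>= 0.4 as the conventional cut for practical relevance.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TestResult",
    "PCAResult",
    "sign_test_two_tailed",
    "fisher_exact_2x2",
    "pca_stage",
    "build_report",
    "LOADING_CUTOFF",
]

LOADING_CUTOFF = 0.4


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    inputs: dict = field(default_factory=dict)


def sign_test_two_tailed(n_a: int, n_b: int) -> TestResult:
    """Exact two-tailed sign test of n_a vs n_b successes at p = 0.5.

    p = min(1, 2 * P(X >= max(n_a, n_b))) for X ~ Binomial(n_a + n_b, 1/2).
    """
    if n_a < 0 or n_b < 0 or n_a + n_b < 1:
        raise ValueError("need non-negative counts with n_a + n_b >= 1")
    n = n_a + n_b
    k = max(n_a, n_b)
    p = min(1.0, 2.0 * float(stats.binom.sf(k - 1, n, 0.5)))
    return TestResult("sign_test_two_tailed", float(k), p,
                      {"n_a": n_a, "n_b": n_b})


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> TestResult:
    """Two-sided Fisher's exact test on [[a, b], [c, d]].

    Two-sided p sums hypergeometric probabilities of all tables with the
    observed margins whose probability does not exceed the observed table's
    (with a small relative slack for float ties). The statistic is the
    sample odds ratio ad/bc.
    """
    table = np.array([[a, b], [c, d]])
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if table.sum() == 0:
        raise ValueError("at least one positive margin required")
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return TestResult("fisher_exact_2x2", float(odds), float(p),
                      {"table": [[a, b], [c, d]]})


@dataclass(frozen=True)
class PCAResult:
    variables: tuple[str, ...]
    loadings: np.ndarray            # variable x component
    variance_fraction: np.ndarray
    scores: np.ndarray              # row x component
    dropped: tuple[str, ...]

    def reportable_loadings(self, cutoff: float = LOADING_CUTOFF
                            ) -> pd.DataFrame:
        rows = []
        for j in range(self.loadings.shape[1]):
            for i, v in enumerate(self.variables):
                if abs(self.loadings[i, j]) >= cutoff:
                    rows.append({"component": j + 1, "variable": v,
                                 "loading": self.loadings[i, j]})
        return pd.DataFrame(rows)

    def loadings_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.loadings, index=list(self.variables),
            columns=[f"PC{j + 1}" for j in range(self.loadings.shape[1])])


def pca_stage(features: pd.DataFrame) -> PCAResult:
    """PCA of a per-male feature table on the correlation matrix.

    Columns are z-scored; zero-variance columns are dropped with a warning.
    Components are eigenvectors of the correlation matrix ordered by
    decreasing eigenvalue; each is sign-flipped so its largest-magnitude
    loading is positive. Scores are the standardized data projected on the
    components (zero mean by construction).
    """
    num = features.select_dtypes(include=[np.number])
    if len(num) < 3:
        raise ValueError("PCA needs at least 3 complete rows")
    if num.isna().any().any():
        raise ValueError("PCA input contains missing values")
    sd = num.std(ddof=1)
    dropped = tuple(sd.index[sd == 0.0])
    if dropped:
        warnings.warn(f"dropping zero-variance columns: {list(dropped)}",
                      stacklevel=2)
        num = num.drop(columns=list(dropped))
    z = (num - num.mean()) / num.std(ddof=1)
    corr = np.corrcoef(z.to_numpy(), rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    for j in range(eigvecs.shape[1]):
        i = np.argmax(np.abs(eigvecs[:, j]))
        if eigvecs[i, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    scores = z.to_numpy() @ eigvecs
    return PCAResult(
        variables=tuple(num.columns),
        loadings=eigvecs,
        variance_fraction=eigvals / eigvals.sum(),
        scores=scores,
        dropped=dropped,
    )


def _md_table(df: pd.DataFrame, floatfmt: str = "{:.4g}") -> str:
    def fmt(v):
        if isinstance(v, float):
            return floatfmt.format(v)
        return "" if v is None or (isinstance(v, float) and np.isnan(v)) else str(v)
    head = "| " + " | ".join(df.columns) + " |"
    sep = "| " + " | ".join("---" for _ in df.columns) + " |"
    rows = ["| " + " | ".join(fmt(v) for v in row) + " |"
            for row in df.itertuples(index=False)]
    return "\n".join([head, sep, *rows])


def build_report(tactics: pd.DataFrame,
                 fidelity: pd.DataFrame | None = None,
                 tests: list[TestResult] | None = None,
                 pca: PCAResult | None = None,
                 config: dict | None = None) -> str:
    """Assemble the self-contained markdown report for one pipeline run."""
    lines: list[str] = ["# Socio-spatial analysis report", ""]
    if config:
        digest = hashlib.sha256(repr(sorted(config.items()))
                                .encode()).hexdigest()[:12]
        lines += [f"Config hash: `{digest}`"]
        if "seed" in config:
            lines += [f"Seed: {config['seed']}"]
        lines += [""]

    lines += ["## Mating tactics", ""]
    n = len(tactics)
    n_res = int((tactics["tactic"] == "resident").sum())
    lines += [f"Males classified: {n} ({n_res} residents, "
              f"{n - n_res} wanderers; "
              f"{100 * n_res / max(n, 1):.1f}% residents)", ""]
    if "surgery" in tactics.columns:
        by = (tactics.groupby("surgery")["tactic"]
              .value_counts().unstack(fill_value=0).reset_index())
        lines += [_md_table(by), ""]

    if fidelity is not None and len(fidelity):
        lines += ["## Resident pair fidelity", "", _md_table(fidelity), ""]

    if tests:
        tdf = pd.DataFrame([{
            "test": t.test_name, "statistic": t.statistic,
            "p_value": t.p_value, "inputs": str(t.inputs),
        } for t in tests])
        lines += ["## Exact tests", "", _md_table(tdf), ""]

    if pca is not None:
        vf = pd.DataFrame({
            "component": [f"PC{j + 1}"
                          for j in range(len(pca.variance_fraction))],
            "variance_fraction": pca.variance_fraction,
        })
        lines += ["## PCA", "", _md_table(vf), "",
                  "Loadings with |value| >= 0.4:", "",
                  _md_table(pca.reportable_loadings()), ""]

    if config:
        cfg = pd.DataFrame(sorted(config.items()), columns=["key", "value"])
        lines += ["## Configuration", "", _md_table(cfg), ""]
    return "\n".join(lines)
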
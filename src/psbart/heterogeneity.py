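"""Posterior summaries of SACE/CSACE and exploratory effect-modification.

Individual effects are summarized over the draws in which the individual was
labelled always-survivor (the effect is undefined outside that stratum); the
"fit-the-fit" step regresses posterior-mean effects on baseline covariates
with a shallow CART to surface candidate effect modifiers.  Subgroup
credible intervals come from the posterior of the node-average effect:
average each retained draw's tau over the leaf's members, then take
quantiles of that series.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import G11
from .gibbs import PosteriorDraws

__all__ = [
    "CsaceSummary",
    "SubgroupTree",
    "TreeNode",
    "summarize_csace",
    "likely_always_survivors",
    "fit_the_fit",
    "render_reports",
]


@dataclass
class CsaceSummary:
    """Per-individual and global posterior summaries."""

    tau_hat: np.ndarray          # posterior mean tau; NaN if never stratum 11
    tau_lo: np.ndarray
    tau_hi: np.ndarray
    available: np.ndarray        # individual labelled 11 in >= 2 draws
    p11: np.ndarray
    sace: float
    sace_ci: tuple[float, float]
    pi_mean: np.ndarray          # posterior mean (pi00, pi10, pi11)
    pi_ci: np.ndarray            # 3 x 2 equal-tailed 95% bounds
    n_draws: int


def summarize_csace(draws: PosteriorDraws) -> CsaceSummary:
    """Equal-tailed 95% summaries of individual effects, SACE and stratum
    proportions from the retained draws."""
    if draws.n_draws < 2:
        raise ValueError("need at least 2 retained draws to summarize")
    tau = draws.tau
    # the effect is defined only within the always-survivor stratum: an
    # individual never labelled 11 has no interpretable tau summary
    available = ((draws.G == G11).any(axis=0)) & \
        (np.sum(~np.isnan(tau), axis=0) >= 2)
    with np.errstate(all="ignore"):
        tau_hat = np.nanmean(tau, axis=0)
        lo = np.nanquantile(tau, 0.025, axis=0)
        hi = np.nanquantile(tau, 0.975, axis=0)
    tau_hat[~available] = np.nan
    lo[~available] = np.nan
    hi[~available] = np.nan
    sace_series = draws.sace[~np.isnan(draws.sace)]
    if sace_series.size == 0:
        sace, sace_ci = float("nan"), (float("nan"), float("nan"))
    else:
        sace = float(sace_series.mean())
        sace_ci = (float(np.quantile(sace_series, 0.025)),
                   float(np.quantile(sace_series, 0.975)))
    pi_ci = np.stack([np.quantile(draws.pi, 0.025, axis=0),
                      np.quantile(draws.pi, 0.975, axis=0)], axis=1)
    return CsaceSummary(
        tau_hat=tau_hat, tau_lo=lo, tau_hi=hi, available=available,
        p11=draws.p11(), sace=sace, sace_ci=sace_ci,
        pi_mean=draws.pi.mean(axis=0), pi_ci=pi_ci, n_draws=draws.n_draws,
    )


def likely_always_survivors(summary: CsaceSummary,
                            q: float = 0.8) -> np.ndarray:
    """Indices of individuals with posterior stratum-11 probability >= q
    (boundary included)."""
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    return np.nonzero(summary.p11 >= q)[0]


# ---------------------------------------------------------------------------
# fit-the-fit subgroup tree
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    members: np.ndarray                  # dataset row indices in this node
    mean: float
    ci: tuple[float, float]
    feature: int | None = None           # None for leaves
    feature_name: str | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def to_dict(self) -> dict:
        d = {"n": int(len(self.members)),
             "members": [int(i) for i in self.members],
             "mean": self.mean, "ci": list(self.ci)}
        if not self.is_leaf:
            d.update(feature=int(self.feature),
                     feature_name=self.feature_name,
                     threshold=float(self.threshold),
                     left=self.left.to_dict(), right=self.right.to_dict())
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        node = cls(members=np.asarray(d["members"], dtype=int),
                   mean=d["mean"], ci=tuple(d["ci"]))
        if "feature" in d:
            node.feature = d["feature"]
            node.feature_name = d.get("feature_name")
            node.threshold = d["threshold"]
            node.left = cls.from_dict(d["left"])
            node.right = cls.from_dict(d["right"])
        return node


@dataclass
class SubgroupTree:
    root: TreeNode
    covariate_names: list[str]

    def leaves(self) -> list[TreeNode]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node)
            else:
                stack.extend((node.left, node.right))
        return out

    def to_json(self) -> str:
        return json.dumps({"covariate_names": self.covariate_names,
                           "root": self.root.to_dict()})

    @classmethod
    def from_json(cls, payload: str) -> "SubgroupTree":
        d = json.loads(payload)
        return cls(root=TreeNode.from_dict(d["root"]),
                   covariate_names=d["covariate_names"])

    def describe(self) -> str:
        lines: list[str] = []

        def _walk(node: TreeNode, indent: int, label: str) -> None:
            pad = "  " * indent
            lines.append(
                f"{pad}{label}n={len(node.members)}  "
                f"mean CSACE={node.mean:.3f}  "
                f"95% CrI [{node.ci[0]:.3f}, {node.ci[1]:.3f}]")
            if not node.is_leaf:
                name = node.feature_name or f"x{node.feature}"
                _walk(node.left, indent + 1,
                      f"{name} <= {node.threshold:.3f}: ")
                _walk(node.right, indent + 1,
                      f"{name} > {node.threshold:.3f}: ")

        _walk(self.root, 0, "")
        return "\n".join(lines)


def _node_ci(draws: PosteriorDraws | None,
             members: np.ndarray, fallback_mean: float
             ) -> tuple[float, float]:
    if draws is None:
        return (fallback_mean, fallback_mean)
    with np.errstate(all="ignore"):
        series = np.nanmean(draws.tau[:, members], axis=1)
    series = series[~np.isnan(series)]
    if series.size < 2:
        return (fallback_mean, fallback_mean)
    return (float(np.quantile(series, 0.025)),
            float(np.quantile(series, 0.975)))


def fit_the_fit(summary: CsaceSummary, members: np.ndarray, X: np.ndarray,
                draws: PosteriorDraws | None = None,
                max_depth: int = 3, min_leaf: int = 20,
                covariate_names: list[str] | None = None) -> SubgroupTree:
    """Greedy variance-reduction CART on (X, posterior-mean tau), restricted
    to the likely always-survivors.

    The tree structure comes from a squared-error CART fit; node means are
    means of member tau-hat, and node credible intervals are posterior
    quantiles of the node-average effect when ``draws`` is supplied.
    """
    from sklearn.tree import DecisionTreeRegressor

    members = np.asarray(members, dtype=int)
    if len(members) < 2 * min_leaf:
        raise ValueError("too few likely always-survivors for a split")
    names = covariate_names or [f"x{j}" for j in range(X.shape[1])]
    y = summary.tau_hat[members]
    Xm = X[members]

    if np.allclose(y, y[0]):
        root = TreeNode(members=members, mean=float(y[0]),
                        ci=_node_ci(draws, members, float(y[0])))
        return SubgroupTree(root=root, covariate_names=names)

    cart = DecisionTreeRegressor(max_depth=max_depth,
                                 min_samples_leaf=min_leaf,
                                 criterion="squared_error",
                                 random_state=0).fit(Xm, y)
    t = cart.tree_

    def _build(node_id: int, rows: np.ndarray) -> TreeNode:
        mean = float(summary.tau_hat[rows].mean())
        node = TreeNode(members=rows, mean=mean,
                        ci=_node_ci(draws, rows, mean))
        if t.children_left[node_id] != -1:
            j = int(t.feature[node_id])
            thr = float(t.threshold[node_id])
            node.feature, node.threshold = j, thr
            node.feature_name = names[j]
            lmask = X[rows, j] <= thr
            node.left = _build(t.children_left[node_id], rows[lmask])
            node.right = _build(t.children_right[node_id], rows[~lmask])
        return node

    return SubgroupTree(root=_build(0, members), covariate_names=names)


# ---------------------------------------------------------------------------
# report rendering
# ---------------------------------------------------------------------------

def render_reports(summary: CsaceSummary, tree: SubgroupTree | None,
                   output_dir: str | Path,
                   members: np.ndarray | None = None) -> dict[str, Path]:
    """Write the per-individual table, the sorted-effect band-plot data and
    the subgroup tree (text + JSON) to ``output_dir``."""
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    table = pd.DataFrame({
        "tau_hat": summary.tau_hat,
        "ci_lower": summary.tau_lo,
        "ci_upper": summary.tau_hi,
        "p_always_survivor": summary.p11,
    })
    path = outdir / "individual_effects.csv"
    table.to_csv(path, index_label="individual")
    written["individual_effects"] = path

    if members is None:
        members = np.nonzero(~np.isnan(summary.tau_hat))[0]
    band = table.iloc[members].dropna(subset=["tau_hat"])
    band = band.sort_values("tau_hat")
    band.insert(0, "rank", np.arange(len(band)))
    path = outdir / "sorted_effects.csv"
    if len(band) == 0:
        path.write_text("no likely always-survivors\n")
    else:
        band.to_csv(path, index_label="individual")
    written["sorted_effects"] = path

    glob = {
        "sace": summary.sace, "sace_ci": list(summary.sace_ci),
        "stratum_proportions": {
            "never_survivor": summary.pi_mean[0],
            "protected": summary.pi_mean[1],
            "always_survivor": summary.pi_mean[2],
        },
        "n_draws": summary.n_draws,
    }
    path = outdir / "global_summary.json"
    path.write_text(json.dumps(glob, indent=2))
    written["global_summary"] = path

    if tree is not None:
        path = outdir / "subgroup_tree.json"
        path.write_text(tree.to_json())
        written["subgroup_tree_json"] = path
        path = outdir / "subgroup_tree.txt"
        path.write_text(tree.describe() + "\n")
        written["subgroup_tree_txt"] = path
    return written
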
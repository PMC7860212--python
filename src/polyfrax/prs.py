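"""Polygenic score construction: LD pruning, thresholded LASSO, scoring.

The score is built the way genome-wide polygenic predictors of continuous
skeletal traits are: variants are pruned so no retained pair on a
chromosome has dosage r^2 above a cutoff (greedy, best p-value first),
LASSO regressions are fit on the variants passing each p-value threshold of
a grid, and the candidate explaining the most phenotypic variance on a
held-out model-selection set wins. Weights are reported on the raw dosage
scale so scoring is a plain weighted allele count; models round-trip
through PGS-Catalog-style scoring files.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import lasso_path

from .synthetic import GenotypeMatrix

logger = logging.getLogger(__name__)

#: p-value threshold grid, most permissive first
DEFAULT_THRESHOLD_GRID = (5e-3, 5e-4, 5e-5, 5e-6, 5e-7, 5e-8)
DEFAULT_R2_MAX = 0.05


@dataclasses.dataclass
class PrsModel:
    """A fitted polygenic score: threshold, penalty, and variant weights.

    ``weights`` has columns variant_id, effect_allele, other_allele, weight
    (per effect-allele dosage on the raw 0-2 scale) and carries only
    nonzero-weight variants. ``r2_select`` is the variance explained on the
    model-selection set and drives between-threshold selection.
    """

    threshold: float
    weights: pd.DataFrame
    lambda_: float
    r2_select: float
    eaf: pd.Series | None = None  # training effect-allele frequencies

    @property
    def n_active(self) -> int:
        return int((self.weights["weight"] != 0).sum())


def _r2_of(pred: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation; 0 for a degenerate prediction."""
    if np.std(pred) == 0 or np.std(y) == 0:
        return 0.0
    return float(np.corrcoef(pred, y)[0, 1] ** 2)


def ld_prune(
    G_train: GenotypeMatrix,
    summaries: pd.DataFrame,
    r2_max: float = DEFAULT_R2_MAX,
) -> list[str]:
    """Greedy LD pruning: retain a variant iff its dosage r^2 with every
    already-retained variant on the same chromosome is <= r2_max.

    Variants are visited in ascending p-value order (variant_id breaks
    ties), so the strongest association in each LD clump survives.
    """
    if not (0 < r2_max <= 1):
        raise ValueError(f"r2_max must be in (0, 1]; got {r2_max}")
    if len(summaries) == 0:
        return []
    known = set(G_train.variant_meta["id"])
    missing = [v for v in summaries["id"] if v not in known]
    if missing:
        raise KeyError(f"variant(s) in summaries absent from genotypes: {missing[:5]}")
    col_of = {v: j for j, v in enumerate(G_train.variant_meta["id"])}
    order = summaries.sort_values(["pvalue", "id"], kind="stable")

    X = G_train.dosages
    Xc = X - X.mean(axis=0)
    norms = np.sqrt(np.einsum("ij,ij->j", Xc, Xc))

    retained: list[str] = []
    retained_by_chrom: dict[str, list[int]] = {}
    chrom_of = dict(zip(summaries["id"], summaries["chrom"].astype(str)))
    for vid in order["id"]:
        j = col_of[vid]
        chrom = chrom_of[vid]
        ok = True
        peers = retained_by_chrom.get(chrom, [])
        if peers and norms[j] > 0:
            r = (Xc[:, peers].T @ Xc[:, j]) / (norms[peers] * norms[j])
            if np.any(r**2 > r2_max):
                ok = False
        elif norms[j] == 0:
            ok = True  # monomorphic: zero correlation with everything
        if ok:
            retained.append(vid)
            retained_by_chrom.setdefault(chrom, []).append(j)
    return retained


def default_lambda_grid(X_std: np.ndarray, y: np.ndarray, n_points: int = 50) -> np.ndarray:
    """50 log-spaced penalties from lambda_max down to lambda_max * 1e-3."""
    n = len(y)
    yc = y - y.mean()
    lam_max = np.abs(X_std.T @ yc).max() / n
    lam_max = max(lam_max, 1e-12)
    return np.geomspace(lam_max, lam_max * 1e-3, n_points)


def fit_candidate(
    G_train: GenotypeMatrix,
    y_train: np.ndarray,
    summaries: pd.DataFrame,
    threshold: float,
    select_G: GenotypeMatrix,
    select_y: np.ndarray,
    pruned_ids: list[str] | None = None,
    lambda_grid: np.ndarray | None = None,
    r2_max: float = DEFAULT_R2_MAX,
) -> PrsModel:
    """LASSO fit at one p-value threshold, with lambda tuned on the
    selection set.

    Dosage columns are standardized for the coordinate-descent fit and the
    weights are mapped back to the raw dosage scale. If no variant passes
    the threshold (after pruning) a null model is returned with a warning.
    """
    y_train = np.asarray(y_train, dtype=float)
    if pruned_ids is None:
        pruned_ids = ld_prune(G_train, summaries, r2_max=r2_max)
    passing = summaries.set_index("id").loc[pruned_ids]
    passing = passing[passing["pvalue"] <= threshold]
    vids = list(passing.index)
    if not vids:
        warnings.warn(
            f"no variant passes threshold {threshold:g}; returning a null model",
            stacklevel=2,
        )
        empty = pd.DataFrame(
            columns=["variant_id", "effect_allele", "other_allele", "weight"]
        )
        return PrsModel(threshold=threshold, weights=empty, lambda_=np.nan, r2_select=0.0)

    col_of = {v: j for j, v in enumerate(G_train.variant_meta["id"])}
    cols = [col_of[v] for v in vids]
    X = G_train.dosages[:, cols]
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xs = (X - mu) / sd
    yc = y_train - y_train.mean()
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(Xs, y_train)
    lambda_grid = np.sort(np.asarray(lambda_grid, dtype=float))[::-1]

    _, coefs, _ = lasso_path(Xs, yc, alphas=lambda_grid, max_iter=5000, tol=1e-6)

    sel_cols = [
        dict(zip(select_G.variant_meta["id"], range(select_G.n_variants)))[v]
        for v in vids
    ]
    Xsel = select_G.dosages[:, sel_cols]
    best = (None, -np.inf)
    raw_coefs = coefs / sd[:, None]  # back to the raw dosage scale
    preds = Xsel @ raw_coefs
    for k, lam in enumerate(lambda_grid):
        r2 = _r2_of(preds[:, k], np.asarray(select_y, dtype=float))
        if r2 > best[1]:
            best = (k, r2)
    k, r2_sel = best
    w = raw_coefs[:, k]
    meta = G_train.variant_meta.set_index("id").loc[vids]
    weights = pd.DataFrame(
        {
            "variant_id": vids,
            "effect_allele": meta["effect_allele"].to_numpy(),
            "other_allele": meta["other_allele"].to_numpy(),
            "weight": w,
        }
    )
    weights = weights[weights["weight"] != 0].reset_index(drop=True)
    eaf = pd.Series(meta["eaf"].to_numpy(), index=vids).loc[weights["variant_id"]]
    return PrsModel(
        threshold=threshold,
        weights=weights,
        lambda_=float(lambda_grid[k]),
        r2_select=max(r2_sel, 0.0),
        eaf=eaf,
    )


def fit_grid(
    G_train: GenotypeMatrix,
    y_train: np.ndarray,
    summaries: pd.DataFrame,
    select_G: GenotypeMatrix,
    select_y: np.ndarray,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLD_GRID,
    r2_max: float = DEFAULT_R2_MAX,
) -> list[PrsModel]:
    """One candidate per p-value threshold (pruning shared across the grid)."""
    pruned = ld_prune(G_train, summaries, r2_max=r2_max)
    return [
        fit_candidate(
            G_train, y_train, summaries, t, select_G, select_y, pruned_ids=pruned
        )
        for t in thresholds
    ]


def select_model(candidates: list[PrsModel]) -> PrsModel:
    """Highest selection-set R^2 wins; ties go to the smaller threshold."""
    if not candidates:
        raise ValueError("no candidate models to select from")
    return min(candidates, key=lambda c: (-c.r2_select, c.threshold))


def score(
    G: GenotypeMatrix,
    model: PrsModel,
    ref_freqs: pd.Series | None = None,
    rescale_missing: bool = False,
) -> np.ndarray:
    """Apply a scoring model: sum of weight x effect-allele dosage.

    Dosages are flipped (2 - d) when the target's effect allele is the
    model's other allele; variants absent from the target contribute
    nothing (subset-sum, no rescaling); per-individual missing genotypes at
    present variants are imputed as 2 x the reference effect-allele
    frequency (model-training frequency when ``ref_freqs`` is omitted).
    Variants whose allele pair matches neither orientation are skipped with
    a logged count; losing more than half the model's variants is an error.
    """
    meta = G.variant_meta.set_index("id")
    scores = np.zeros(G.n_individuals)
    col_of = {v: j for j, v in enumerate(G.variant_meta["id"])}
    n_mismatch = 0
    n_present = 0
    used_mass = 0.0
    for row in model.weights.itertuples(index=False):
        vid = row.variant_id
        if vid not in col_of:
            continue
        target = meta.loc[vid]
        if (target["effect_allele"], target["other_allele"]) == (
            row.effect_allele,
            row.other_allele,
        ):
            flip = False
        elif (target["effect_allele"], target["other_allele"]) == (
            row.other_allele,
            row.effect_allele,
        ):
            flip = True
        else:
            n_mismatch += 1
            continue
        n_present += 1
        d = G.dosages[:, col_of[vid]].copy()
        if np.isnan(d).any():
            if ref_freqs is not None and vid in ref_freqs.index:
                f = float(ref_freqs.loc[vid])
            elif model.eaf is not None and vid in model.eaf.index:
                f = float(model.eaf.loc[vid])
            else:
                f = float(np.nanmean(d)) / 2.0
            fill = 2.0 * (1.0 - f) if flip else 2.0 * f
            d = np.where(np.isnan(d), fill, d)
        if flip:
            d = 2.0 - d
        scores += row.weight * d
        used_mass += abs(row.weight)
    n_model = len(model.weights)
    if n_mismatch:
        logger.warning("skipped %d variant(s) with unresolvable alleles", n_mismatch)
    if n_model and n_mismatch > 0.5 * n_model:
        raise ValueError(
            f"{n_mismatch}/{n_model} model variants have unresolvable alleles"
        )
    if rescale_missing and n_model:
        total_mass = float(model.weights["weight"].abs().sum())
        if 0 < used_mass < total_mass:
            scores = scores * (total_mass / used_mass)
    return scores


# ---------------------------------------------------------------------------
# scoring-file IO (PGS-Catalog scoring file layout)

_SCORING_COLUMNS = [
    "rsID",
    "chr_name",
    "chr_position",
    "effect_allele",
    "other_allele",
    "effect_weight",
]


def write_scoring_file(
    model: PrsModel,
    path: str | Path,
    variant_meta: pd.DataFrame | None = None,
) -> None:
    """Write the model as a tab-delimited scoring file with '#' metadata
    header lines and the standard column set."""
    path = Path(path)
    if variant_meta is not None:
        pos = variant_meta.set_index("id")
    with open(path, "w") as fh:
        fh.write("#format=PGS-scoring-file\n")
        fh.write(f"#pvalue_threshold={model.threshold:g}\n")
        fh.write(f"#lambda={model.lambda_:g}\n")
        fh.write(f"#r2_select={model.r2_select:.10g}\n")
        fh.write("\t".join(_SCORING_COLUMNS) + "\n")
        for row in model.weights.itertuples(index=False):
            if variant_meta is not None and row.variant_id in pos.index:
                chrom = pos.loc[row.variant_id, "chrom"]
                position = pos.loc[row.variant_id, "pos"]
            else:
                chrom, position = "NA", "NA"
            fh.write(
                f"{row.variant_id}\t{chrom}\t{position}\t{row.effect_allele}\t"
                f"{row.other_allele}\t{row.weight!r}\n"
            )


def read_scoring_file(path: str | Path) -> PrsModel:
    """Parse a scoring file; unknown extra columns are ignored, malformed
    headers or non-numeric weights are rejected with the line number."""
    path = Path(path)
    threshold = np.nan
    lambda_ = np.nan
    r2_select = 0.0
    header: list[str] | None = None
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if "=" in line:
                    key, _, val = line[1:].partition("=")
                    if key == "pvalue_threshold":
                        threshold = float(val)
                    elif key == "lambda":
                        lambda_ = float(val)
                    elif key == "r2_select":
                        r2_select = float(val)
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                required = {"rsID", "effect_allele", "other_allele", "effect_weight"}
                missing = required - set(header)
                if missing:
                    raise ValueError(
                        f"line {lineno}: malformed scoring-file header, missing {sorted(missing)}"
                    )
                continue
            rec = dict(zip(header, fields))
            try:
                weight = float(rec["effect_weight"])
            except (ValueError, KeyError) as exc:
                raise ValueError(
                    f"line {lineno}: non-numeric effect_weight {rec.get('effect_weight')!r}"
                ) from exc
            rows.append(
                (rec["rsID"], rec["effect_allele"], rec["other_allele"], weight)
            )
    if header is None:
        raise ValueError("scoring file has no header line")
    weights = pd.DataFrame(
        rows, columns=["variant_id", "effect_allele", "other_allele", "weight"]
    )
    return PrsModel(
        threshold=threshold, weights=weights, lambda_=lambda_, r2_select=r2_select
    )
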
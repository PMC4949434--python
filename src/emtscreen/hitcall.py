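"""Phenotype clustering, phenotypic-strength hit calling and screen evaluation.

After normalisation, every valid, non-toxic well is a point in z-space.
k-means (k = 5 by default) separates the phenotype classes; the cluster
holding the strong positive-control wells is the EMT-reversal cluster; a
well is a hit iff it belongs to that cluster *and* its phenotypic strength
(Euclidean distance to the negative-control centroid) exceeds the threshold
(strictly greater than 15 by default).  Per-well hits are condensed to
unique compounds by the any-well rule, and the screen is scored as TPR over
strong positive-control wells, FPR over vehicle wells and the library hit
rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .screenqc import negative_centroid


@dataclass
class HitCallConfig:
    k: int = 5                   # phenotype clusters
    strength_threshold: float = 15.0
    n_init: int = 25             # k-means restarts
    min_nuclei: float = 10.0     # toxicity / validity floor
    n_top_concentrations: int = 2  # ladder points defining "strong" controls
    majority_floor: float = 0.4  # minimum control fraction for a clean EMT cluster


def phenotypic_strength(z_profiles: np.ndarray, neg_centroid: np.ndarray) -> np.ndarray:
    """Euclidean distance of each z-profile to the negative-control centroid."""
    z = np.atleast_2d(np.asarray(z_profiles, dtype=float))
    c = np.asarray(neg_centroid, dtype=float)
    if z.shape[1] != c.shape[0]:
        raise ValueError("profile/centroid dimension mismatch")
    return np.linalg.norm(z - c, axis=1)


def exclude_toxic(records: pd.DataFrame, min_nuclei: float = 10.0,
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split wells into the clean stream and the toxic/failed stream.

    A well goes to the toxic stream when its nuclei count falls below
    ``min_nuclei`` or its validity flag is 0; those wells never enter
    clustering and can never become hits.
    """
    if "nuclei_count" not in records.columns:
        raise ValueError("records lack a nuclei_count parameter")
    toxic_mask = records["nuclei_count"] < min_nuclei
    if "valid_field" in records.columns:
        toxic_mask |= records["valid_field"] < 0.5
    return records[~toxic_mask].copy(), records[toxic_mask].copy()


def cluster_profiles(z_profiles: np.ndarray, k: int = 5, seed: int = 0,
                     n_init: int = 25) -> tuple[np.ndarray, np.ndarray]:
    """k-means phenotype clustering (k-means++ init, best of ``n_init`` restarts).

    Deterministic given ``seed``.  Degenerate data (fewer distinct points
    than k) simply leaves some clusters empty-ish; that is reported by the
    caller, not fatal here.
    """
    z = np.asarray(z_profiles, dtype=float)
    if z.ndim != 2:
        raise ValueError("expected a 2-D (wells x parameters) matrix")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed)
    labels = km.fit_predict(z)
    return labels, km.cluster_centers_


def strong_positive_mask(records: pd.DataFrame, n_top: int = 2) -> pd.Series:
    """Wells at the top ``n_top`` ladder concentrations of each positive control."""
    mask = pd.Series(False, index=records.index)
    pos = records[records["role"] == "pos_control"]
    for _, grp in pos.groupby("compound_id"):
        top = sorted(grp["concentration_uM"].unique())[-n_top:]
        mask.loc[grp.index[grp["concentration_uM"].isin(top)]] = True
    return mask


@dataclass
class EmtClusterResult:
    cluster_id: int
    control_fraction: float
    needs_review: bool


def identify_emt_cluster(assignments: np.ndarray, strong_control_mask: np.ndarray,
                         strengths: np.ndarray, majority_floor: float = 0.4,
                         ) -> EmtClusterResult:
    """The cluster holding the strong positive controls.

    Picks the cluster containing the largest fraction of strong-control
    wells; ties break towards the higher median control strength within the
    cluster.  If no cluster reaches ``majority_floor`` of the controls the
    run is flagged for manual review (but the best cluster is still
    returned).
    """
    assignments = np.asarray(assignments)
    mask = np.asarray(strong_control_mask, dtype=bool)
    strengths = np.asarray(strengths, dtype=float)
    if not mask.any():
        raise ValueError("no strong positive-control wells in the clustered set")
    ctrl = assignments[mask]
    ids, counts = np.unique(ctrl, return_counts=True)
    fracs = counts / mask.sum()
    best = fracs.max()
    tied = ids[fracs == best]
    if len(tied) > 1:
        med = [np.median(strengths[mask & (assignments == cid)]) for cid in tied]
        winner = int(tied[int(np.argmax(med))])
    else:
        winner = int(tied[0])
    return EmtClusterResult(cluster_id=winner, control_fraction=float(best),
                            needs_review=bool(best < majority_floor))


def call_hits(assignments: np.ndarray, strengths: np.ndarray, emt_cluster: int,
              threshold: float = 15.0) -> np.ndarray:
    """Per-well hit flags: in the EMT cluster *and* strength strictly above T."""
    assignments = np.asarray(assignments)
    strengths = np.asarray(strengths, dtype=float)
    return (assignments == emt_cluster) & (strengths > threshold)


def condense_to_compounds(records: pd.DataFrame) -> pd.DataFrame:
    """Per-compound hit list by the any-well rule.

    A compound is a hit iff any of its wells is a hit; the compound score is
    its maximum strength.  Returns one row per hit compound, deduplicated and
    sorted by max strength descending.
    """
    hits = records[records["is_hit"]]
    if hits.empty:
        return pd.DataFrame(columns=["compound_id", "max_strength", "n_hit_wells",
                                     "n_wells"])
    grouped = hits.groupby("compound_id")
    out = pd.DataFrame({
        "max_strength": grouped["strength"].max(),
        "n_hit_wells": grouped.size(),
    })
    n_wells = records.groupby("compound_id").size()
    out["n_wells"] = n_wells.reindex(out.index)
    out = out.sort_values("max_strength", ascending=False).reset_index()
    return out[["compound_id", "max_strength", "n_hit_wells", "n_wells"]]


@dataclass
class ScreenEvaluation:
    tpr_pct: float
    fpr_pct: float
    hit_rate_pct: float
    active_recovery_pct: float = float("nan")
    n_toxic_hits: int = 0

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("tpr_pct", "fpr_pct", "hit_rate_pct", "active_recovery_pct",
                 "n_toxic_hits")}


def evaluate_screen(records: pd.DataFrame, hit_compounds: pd.DataFrame,
                    strong_mask: pd.Series, truth=None) -> ScreenEvaluation:
    """TPR / FPR / hit-rate accounting, percentages to one decimal.

    TPR: hit-flagged wells among strong positive-control wells.  FPR:
    hit-flagged wells among vehicle (DMSO) wells.  Hit rate: hit compounds
    over library compounds.  With ground truth, also the fraction of planted
    active compounds recovered and the count of planted-toxic compounds that
    leaked into the hit list (should be zero by construction).
    """
    def pct(num: int, den: int) -> float:
        return round(100.0 * num / den, 1) if den else float("nan")

    strong = records[strong_mask.reindex(records.index, fill_value=False)]
    tpr = pct(int(strong["is_hit"].sum()), len(strong))
    dmso = records[records["role"] == "neg_dmso"]
    fpr = pct(int(dmso["is_hit"].sum()), len(dmso))
    lib = records[records["role"] == "library"]
    n_lib_compounds = lib["compound_id"].nunique()
    lib_hits = set(hit_compounds["compound_id"]) & set(lib["compound_id"])
    hit_rate = pct(len(lib_hits), n_lib_compounds)
    ev = ScreenEvaluation(tpr_pct=tpr, fpr_pct=fpr, hit_rate_pct=hit_rate)
    if truth is not None:
        recovered = set(hit_compounds["compound_id"]) & set(truth.active_compounds)
        ev.active_recovery_pct = pct(len(recovered), len(truth.active_compounds))
        ev.n_toxic_hits = len(set(hit_compounds["compound_id"]) & truth.toxic_compounds)
    return ev


def verification_rate(n_verified: int, n_hits: int) -> int:
    """Verified fraction of primary hits, as a whole percentage."""
    if n_hits <= 0:
        raise ValueError("n_hits must be positive")
    return int(round(100.0 * n_verified / n_hits))


@dataclass
class HitCallResult:
    records: pd.DataFrame               # clean wells + cluster/strength/is_hit
    toxic_records: pd.DataFrame
    hit_compounds: pd.DataFrame
    emt_cluster: EmtClusterResult
    centroids: np.ndarray
    evaluation: ScreenEvaluation | None = None


def run_hit_calling(normalized: pd.DataFrame, z_params: list[str],
                    config: HitCallConfig | None = None, seed: int = 0,
                    truth=None) -> HitCallResult:
    """The full hit-calling stage on a normalised screen table."""
    from .platenorm import Z_PREFIX

    cfg = config or HitCallConfig()
    clean, toxic = exclude_toxic(normalized, cfg.min_nuclei)
    cols = [Z_PREFIX + p for p in z_params]
    z = clean[cols].to_numpy(dtype=float)
    finite = np.all(np.isfinite(z), axis=1)
    clean = clean[finite].copy()
    z = z[finite]
    neg = z[(clean["role"] == "neg_dmso").to_numpy()]
    centroid = negative_centroid(neg)
    strengths = phenotypic_strength(z, centroid)
    labels, centers = cluster_profiles(z, cfg.k, seed=seed, n_init=cfg.n_init)
    clean["cluster"] = labels
    clean["strength"] = strengths
    strong = strong_positive_mask(clean, cfg.n_top_concentrations)
    emt = identify_emt_cluster(labels, strong.to_numpy(), strengths,
                               cfg.majority_floor)
    clean["is_hit"] = call_hits(labels, strengths, emt.cluster_id,
                                cfg.strength_threshold)
    hit_compounds = condense_to_compounds(
        clean[clean["role"] == "library"][["compound_id", "strength", "is_hit"]])
    evaluation = evaluate_screen(clean, hit_compounds, strong, truth)
    return HitCallResult(records=clean, toxic_records=toxic,
                         hit_compounds=hit_compounds, emt_cluster=emt,
                         centroids=centers, evaluation=evaluation)
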
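"""Scoring of extracted signatures and fitted activities.

Implements the evaluation statistics used throughout the package: cosine
distance between mutation-type distributions, threshold matching of
predicted against ground-truth signatures with duplicate / not-matched
accounting, the reconstruction rate of a fitted decomposition, expected
per-signature mutation attribution, and banded nearest-neighbor mapping of
predictions onto a catalogue of known signatures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalog import ActivityMatrix, MutationCatalog, SignatureSet


def cosine_distance(u, v) -> float:
    """``1 - u.v / (|u| |v|)`` for non-negative, non-zero vectors.

    Ranges over [0, 1] for non-negative inputs: 0 for parallel vectors, 1
    for disjoint supports.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine distance is undefined for a zero vector")
    return float(1.0 - np.dot(u, v) / (nu * nv))


def _distance_matrix(a: SignatureSet, b: SignatureSet) -> np.ndarray:
    pa = a.probs / np.linalg.norm(a.probs, axis=1, keepdims=True)
    pb = b.probs / np.linalg.norm(b.probs, axis=1, keepdims=True)
    return 1.0 - pa @ pb.T


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching predicted signatures to ground truth.

    ``pairs`` holds the accepted one-to-one matches as (predicted index,
    truth index, cosine distance).  Every predicted signature is accounted
    for exactly once: ``correct_matched + duplicated + not_matched`` equals
    the number of predictions.  ``duplicated`` counts extra predictions
    whose nearest truth was already claimed by a closer prediction;
    ``not_matched`` counts predictions with no truth within the threshold.
    ``truth_nearest`` reports, for every truth signature, its nearest
    prediction and distance (the reverse matching direction).
    """

    pairs: tuple[tuple[int, int, float], ...]
    correct_matched: int
    duplicated: int
    not_matched: int
    unmatched_truths: tuple[int, ...]
    truth_nearest: tuple[tuple[int, int, float], ...]
    threshold: float

    def to_frame(self, predicted_names=None, truth_names=None) -> pd.DataFrame:
        rows = [
            {
                "predicted": predicted_names[p] if predicted_names else p,
                "truth": truth_names[t] if truth_names else t,
                "cosine_distance": d,
                "cosine_similarity": 1.0 - d,
            }
            for p, t, d in self.pairs
        ]
        return pd.DataFrame(rows, columns=["predicted", "truth", "cosine_distance", "cosine_similarity"])


def match_signatures(
    predicted: SignatureSet,
    truth: SignatureSet,
    threshold: float = 0.1,
    *,
    method: str = "greedy",
) -> MatchResult:
    """Match predicted signatures to truth at a cosine-distance threshold.

    Each prediction is a candidate for its nearest truth if that distance is
    at most ``threshold``; candidates are resolved one-to-one in ascending
    distance order.  A prediction losing its (already claimed) nearest truth
    counts as duplicated; one with no truth within the threshold counts as
    not matched.  ``method='hungarian'`` instead resolves candidates by
    minimum-total-distance assignment (scipy), as a sensitivity check; the
    duplicate semantics are unchanged.
    """
    if predicted.K == 0 or truth.K == 0:
        raise ValueError("both signature sets must be non-empty")
    dist = _distance_matrix(predicted, truth)
    nearest = dist.argmin(axis=1)
    nearest_d = dist[np.arange(predicted.K), nearest]
    candidates = [p for p in range(predicted.K) if nearest_d[p] <= threshold]

    pairs: list[tuple[int, int, float]] = []
    duplicated = 0
    claimed: set[int] = set()
    if method == "greedy":
        for p in sorted(candidates, key=lambda p: nearest_d[p]):
            t = int(nearest[p])
            if t in claimed:
                duplicated += 1
            else:
                claimed.add(t)
                pairs.append((p, t, float(nearest_d[p])))
    elif method == "hungarian":
        from scipy.optimize import linear_sum_assignment

        if candidates:
            sub = dist[np.ix_(candidates, range(truth.K))]
            big = 10.0  # sentinel larger than any admissible distance
            cost = np.where(sub <= threshold, sub, big)
            ri, ci = linear_sum_assignment(cost)
            assigned = {}
            for i, t in zip(ri, ci):
                if cost[i, t] <= threshold:
                    assigned[candidates[i]] = int(t)
            for p in candidates:
                if p in assigned:
                    t = assigned[p]
                    claimed.add(t)
                    pairs.append((p, t, float(dist[p, t])))
                else:
                    duplicated += 1
    else:
        raise ValueError(f"unknown matching method {method!r}")

    pairs.sort(key=lambda pt: pt[2])
    not_matched = predicted.K - len(candidates)
    truth_nearest = tuple(
        (int(t), int(dist[:, t].argmin()), float(dist[:, t].min())) for t in range(truth.K)
    )
    return MatchResult(
        pairs=tuple(pairs),
        correct_matched=len(pairs),
        duplicated=duplicated,
        not_matched=not_matched,
        unmatched_truths=tuple(t for t in range(truth.K) if t not in claimed),
        truth_nearest=truth_nearest,
        threshold=threshold,
    )


def reconstruction_rate(
    catalog: MutationCatalog, theta: ActivityMatrix, phi: SignatureSet
) -> tuple[float, dict[str, float]]:
    """Min-overlap reconstruction rate of a fitted decomposition.

    For each sample the overlap between observed counts ``M_v`` and
    predicted expected counts ``n * (theta phi)_v`` is
    ``sum_v min(M_v, n (theta phi)_v) / n``; samples are averaged within
    each tumor type and tumor types are averaged with equal weight
    regardless of size.  Returns the global rate and the per-type rates.
    A rate of 1.0 means every sample's catalog is reproduced exactly.
    """
    if theta.K != phi.K:
        raise ValueError("theta and phi disagree on the number of signatures")
    if len(theta.sample_ids) != catalog.n_samples:
        raise ValueError("theta rows do not match the catalog samples")
    n = catalog.n_mutations
    if (n == 0).any():
        raise ValueError("zero-mutation samples must be filtered before evaluating")
    predicted = theta.values @ phi.probs  # (N, 96) probabilities
    per_sample = np.minimum(catalog.counts, n[:, None] * predicted).sum(axis=1) / n
    per_type = {
        t: float(per_sample[catalog.samples_of_type(l)].mean())
        for l, t in enumerate(catalog.tumor_types)
    }
    rr_global = float(np.mean(list(per_type.values())))
    return rr_global, per_type


def attributed_mutations(catalog: MutationCatalog, theta: ActivityMatrix) -> pd.DataFrame:
    """Expected mutations attributed to each signature: ``xi_lsk = n_ls theta_lsk``.

    Returns a tidy table (sample_id, tumor_type, signature, attributed)
    whose per-sample totals equal n_ls; this is the data behind per-type and
    per-signature activity summaries.
    """
    if len(theta.sample_ids) != catalog.n_samples:
        raise ValueError("theta rows do not match the catalog samples")
    xi = catalog.n_mutations[:, None] * theta.values
    wide = pd.DataFrame(xi, columns=list(theta.signature_names))
    wide.insert(0, "tumor_type", list(catalog.sample_tumor_types()))
    wide.insert(0, "sample_id", list(catalog.sample_ids))
    return wide.melt(
        id_vars=["sample_id", "tumor_type"], var_name="signature", value_name="attributed"
    )


#: Band labels for nearest-known mapping; intervals are right-open, so a
#: distance of exactly 0.1 falls in the middle band and 0.2 in the last.
_BANDS = ((0.1, "<0.1"), (0.2, "[0.1,0.2)"), (np.inf, ">=0.2"))


def map_to_known(predicted: SignatureSet, known: SignatureSet) -> pd.DataFrame:
    """Nearest known signature for every prediction, with distance banding.

    Many-to-one mapping is allowed: several predictions may map to the same
    known signature.  Bands follow the 0.1 / 0.2 cosine-distance cuts.
    """
    if known.K == 0:
        raise ValueError("known signature set must be non-empty")
    dist = _distance_matrix(predicted, known)
    nearest = dist.argmin(axis=1)
    rows = []
    for p in range(predicted.K):
        d = float(dist[p, nearest[p]])
        band = next(label for cut, label in _BANDS if d < cut)
        rows.append(
            {
                "predicted": predicted.names[p],
                "nearest_known": known.names[int(nearest[p])],
                "cosine_distance": d,
                "band": band,
            }
        )
    return pd.DataFrame(rows, columns=["predicted", "nearest_known", "cosine_distance", "band"])
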
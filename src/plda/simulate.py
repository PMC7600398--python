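"""Generative simulator for artificial mutation catalogs.

Catalogs are drawn from the PLDA generative process itself: per sample,
activities ``theta ~ Dirichlet(alpha_l)`` where ``alpha_lk`` is 0.5 for
signatures designated active in tumor type l and 0.05 for inactive ones
(so active signatures are expected to be 10x more active); per-signature
mutation counts ``~ Multinomial(n_ls, theta)``; and mutation-type counts
``~ Multinomial(., phi_k)`` summed over signatures.  Ground truth (theta,
phi, per-signature mutation counts) is returned alongside every catalog so
recovery can be scored.

Two benchmark designs are built in: a 5-tumor-type / 5-signature design with
two active signatures per type arranged cyclically, and a harder 10x10
design that appends five tumor types with only two samples each, one private
signature per added type.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

from .catalog import ActivityMatrix, MutationCatalog, SignatureSet
from .evaluate import cosine_distance
from .sbs96 import N_TYPES


@dataclass(frozen=True)
class ScenarioDesign:
    """Which signatures are active in which virtual tumor type, plus sizes.

    ``active`` is an (L, K_true) boolean matrix; active cells get Dirichlet
    concentration ``alpha_active`` (default 0.5), inactive cells
    ``alpha_inactive`` (default 0.05).  ``samples_per_type`` may vary by
    type; ``mutations_per_sample`` is constant across the scenario.
    """

    active: np.ndarray                  # (L, K_true) bool
    signatures: SignatureSet
    samples_per_type: np.ndarray        # (L,) int
    mutations_per_sample: int = 1000
    alpha_active: float = 0.5
    alpha_inactive: float = 0.05
    tumor_type_labels: tuple[str, ...] = ()

    def __post_init__(self):
        act = np.asarray(self.active, dtype=bool)
        if act.ndim != 2:
            raise ValueError("active must be an (L, K) boolean matrix")
        object.__setattr__(self, "active", act)
        if act.shape[1] != self.signatures.K:
            raise ValueError(
                f"design has {act.shape[1]} signature columns but "
                f"{self.signatures.K} signature distributions"
            )
        if not act.any(axis=1).all():
            raise ValueError("every tumor type must have at least one active signature")
        if not (self.alpha_active > self.alpha_inactive > 0):
            raise ValueError("need alpha_active > alpha_inactive > 0")
        spt = np.broadcast_to(np.asarray(self.samples_per_type, dtype=int), (act.shape[0],))
        if (spt < 1).any():
            raise ValueError("every tumor type needs at least one sample")
        object.__setattr__(self, "samples_per_type", spt.copy())
        if self.mutations_per_sample < 1:
            raise ValueError("mutations_per_sample must be positive")
        labels = self.tumor_type_labels or tuple(
            f"Type_{l + 1}" for l in range(act.shape[0])
        )
        if len(labels) != act.shape[0]:
            raise ValueError("one tumor-type label per design row required")
        object.__setattr__(self, "tumor_type_labels", tuple(labels))

    @property
    def L(self) -> int:
        return self.active.shape[0]

    @property
    def K_true(self) -> int:
        return self.active.shape[1]

    def alpha(self) -> np.ndarray:
        """The (L, K_true) Dirichlet concentration matrix the design encodes."""
        return np.where(self.active, self.alpha_active, self.alpha_inactive)

    # Designs serialize without the signature distributions by default; the
    # signature TSV travels separately through catalog_io.
    def to_dict(self, include_signatures: bool = True) -> dict:
        d = {
            "active": self.active.astype(int).tolist(),
            "samples_per_type": self.samples_per_type.tolist(),
            "mutations_per_sample": int(self.mutations_per_sample),
            "alpha_active": float(self.alpha_active),
            "alpha_inactive": float(self.alpha_inactive),
            "tumor_type_labels": list(self.tumor_type_labels),
        }
        if include_signatures:
            d["signature_names"] = list(self.signatures.names)
            d["signature_probs"] = self.signatures.probs.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict, signatures: SignatureSet | None = None) -> "ScenarioDesign":
        if signatures is None:
            signatures = SignatureSet(
                names=tuple(d["signature_names"]),
                probs=np.asarray(d["signature_probs"], dtype=float),
            )
        return cls(
            active=np.asarray(d["active"], dtype=bool),
            signatures=signatures,
            samples_per_type=np.asarray(d["samples_per_type"], dtype=int),
            mutations_per_sample=int(d["mutations_per_sample"]),
            alpha_active=float(d.get("alpha_active", 0.5)),
            alpha_inactive=float(d.get("alpha_inactive", 0.05)),
            tumor_type_labels=tuple(d.get("tumor_type_labels", ())),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path, signatures: SignatureSet | None = None) -> "ScenarioDesign":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh), signatures=signatures)


@dataclass(frozen=True)
class GroundTruth:
    theta_true: ActivityMatrix
    phi_true: SignatureSet
    z_counts: np.ndarray  # (N, K_true) int — mutations drawn from each signature


def generate_catalog(design: ScenarioDesign, seed: int) -> tuple[MutationCatalog, GroundTruth]:
    """Draw one catalog (and its ground truth) from the generative process.

    Counts are drawn hierarchically — per-signature totals first, then
    per-signature mutation-type counts — which is distributionally identical
    to drawing mutations one at a time and directly yields the
    per-signature attribution truth.
    """
    rng = np.random.default_rng(seed)
    alpha = design.alpha()
    phi = design.signatures.probs
    n = design.mutations_per_sample

    ids, labels, thetas, zs, counts = [], [], [], [], []
    for l in range(design.L):
        label = design.tumor_type_labels[l]
        for s in range(int(design.samples_per_type[l])):
            theta = rng.dirichlet(alpha[l])
            z = rng.multinomial(n, theta)
            c = np.zeros(N_TYPES, dtype=np.int64)
            for k in np.flatnonzero(z):
                c += rng.multinomial(z[k], phi[k])
            ids.append(f"{label}_s{s + 1:04d}")
            labels.append(label)
            thetas.append(theta)
            zs.append(z)
            counts.append(c)

    catalog = MutationCatalog.from_samples(ids, labels, np.array(counts))
    truth = GroundTruth(
        theta_true=ActivityMatrix(
            sample_ids=tuple(ids),
            tumor_types=tuple(labels),
            signature_names=design.signatures.names,
            values=np.array(thetas),
        ),
        phi_true=design.signatures,
        z_counts=np.array(zs),
    )
    return catalog, truth


def five_type_scenario(
    signatures: SignatureSet,
    *,
    samples_per_type: int = 100,
    mutations_per_sample: int = 1000,
) -> ScenarioDesign:
    """The 5-type / 5-signature benchmark design.

    Tumor type l (1-based) has signatures {l, l+1 (mod 5)} active, so
    adjacent types share exactly one active signature.  Defaults are the
    benchmark sizes: 100 samples per type, 1000 mutations per sample.
    """
    if signatures.K < 5:
        raise ValueError("the five-type design needs at least 5 signatures")
    sigs = SignatureSet(names=signatures.names[:5], probs=signatures.probs[:5])
    active = np.zeros((5, 5), dtype=bool)
    for l in range(5):
        active[l, l] = True
        active[l, (l + 1) % 5] = True
    return ScenarioDesign(
        active=active,
        signatures=sigs,
        samples_per_type=np.full(5, samples_per_type),
        mutations_per_sample=mutations_per_sample,
    )


def rare_type_scenario(
    signatures: SignatureSet,
    *,
    samples_per_type: int = 100,
    samples_per_small_type: int = 2,
    mutations_per_sample: int = 1000,
) -> ScenarioDesign:
    """The harder 10-type / 10-signature design with five small tumor types.

    Types 1-5 reproduce the cyclic two-active pattern over signatures 1-5;
    types 6-10 each have a single private active signature (6th-10th) and
    only two samples, emulating rare tumor types.
    """
    if signatures.K < 10:
        raise ValueError("the rare-type design needs at least 10 signatures")
    sigs = SignatureSet(names=signatures.names[:10], probs=signatures.probs[:10])
    active = np.zeros((10, 10), dtype=bool)
    for l in range(5):
        active[l, l] = True
        active[l, (l + 1) % 5] = True
    for l in range(5, 10):
        active[l, l] = True
    spt = np.concatenate([
        np.full(5, samples_per_type), np.full(5, samples_per_small_type)
    ])
    return ScenarioDesign(
        active=active,
        signatures=sigs,
        samples_per_type=spt,
        mutations_per_sample=mutations_per_sample,
    )


def make_surrogate_signatures(
    K: int,
    min_pairwise_cosine_distance: float = 0.6,
    seed: int = 0,
    *,
    concentration: float = 0.05,
    max_attempts: int = 10000,
) -> SignatureSet:
    """Rejection-sample K sparse random signatures with a separation floor.

    Candidates are Dirichlet(0.05) draws over the 96 types — sparse, peaky
    distributions resembling real signatures — accepted only if their cosine
    distance to every already-accepted signature is at least the floor.
    Deterministic given the seed.
    """
    if K < 1:
        raise ValueError("K must be at least 1")
    if not 0 <= min_pairwise_cosine_distance < 1:
        raise ValueError("min_pairwise_cosine_distance must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    accepted: list[np.ndarray] = []
    for _ in range(max_attempts):
        cand = rng.dirichlet(np.full(N_TYPES, concentration))
        if all(cosine_distance(cand, p) >= min_pairwise_cosine_distance for p in accepted):
            accepted.append(cand)
            if len(accepted) == K:
                break
    else:
        raise RuntimeError(
            f"could not place {K} signatures with pairwise cosine distance >= "
            f"{min_pairwise_cosine_distance} in {max_attempts} attempts; lower the floor"
        )
    return SignatureSet(
        names=tuple(f"Surrogate_{k + 1}" for k in range(K)),
        probs=np.array(accepted),
    )


def write_ground_truth(truth: GroundTruth, out_dir, label: str = "truth") -> None:
    """Write theta/phi/z-count sidecars next to a generated catalog."""
    from pathlib import Path

    from .catalog import write_activities, write_signature_set

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_activities(truth.theta_true, out / f"{label}_theta.tsv")
    write_signature_set(truth.phi_true, out / f"{label}_phi.tsv")
    import pandas as pd

    z = pd.DataFrame(truth.z_counts, columns=list(truth.phi_true.names))
    z.insert(0, "tumor_type", list(truth.theta_true.tumor_types))
    z.insert(0, "sample_id", list(truth.theta_true.sample_ids))
    z.to_csv(out / f"{label}_z_counts.tsv", sep="\t", index=False, lineterminator="\n")
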
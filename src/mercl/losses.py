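"""Shared-space projection and the MERCL contrastive objectives.

Spatiotemporal representations are pooled over time, projected into a shared
embedding space by a per-modality linear map ``z_m = W_m h_m`` and (by
default) L2-normalized.  Three supervised contrastive terms then act on the
embeddings of a mini-batch:

* **AMCL** (intra-modal): for each anchor, same-class embeddings of the
  *same* modality are positives, different-class ones negatives.
* **EMCL** (inter-modal): positives/negatives are drawn from the two
  *other* modalities (2N positives, 2M negatives per anchor).
* **SMCL** (sample-wise alignment): the anchor's own other-modality
  embeddings are pulled toward a similarity margin ``alpha``,
  ``L = 1/2 * sum_i (s_i - alpha)^2``; silent-audio embeddings are excluded
  before pair construction.

The printed ratio losses use raw inner products inside a logarithm, which is
only defined when the sums are positive; the default "softened" form maps
each similarity through ``exp(s / tau)`` (on normalized embeddings), keeping
the ratio structure while guaranteeing a finite loss.  ``literal_mode``
evaluates the raw form and raises if its domain is violated.

The combined objective is ``L_MERCL = l1*L_AMCL + l2*L_EMCL + l3*L_SMCL``
with the expectation over anchors taken as the mean over all valid anchors
in the batch and over the three anchor modalities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._tensor import Tensor
from .nn import Module, Linear

__all__ = [
    "MODALITIES", "MerclWeights", "ProjectionHead", "project",
    "ContrastiveSet", "build_pairs", "amcl_loss", "emcl_loss", "smcl_loss",
    "mercl_loss", "MerclResult", "LiteralDomainError",
]

MODALITIES = ("video", "audio", "eeg")


class LiteralDomainError(ValueError):
    """Raised when the raw ratio loss hits a nonpositive numerator/denominator."""


@dataclass
class MerclWeights:
    lambda_amcl: float = 1.0
    lambda_emcl: float = 1.0
    lambda_smcl: float = 1.0
    alpha: float = 0.8
    temperature: float = 0.1
    literal_mode: bool = False
    normalized: bool = True

    def __post_init__(self):
        lams = (self.lambda_amcl, self.lambda_emcl, self.lambda_smcl)
        if any(l < 0 for l in lams):
            raise ValueError("loss weights must be nonnegative")
        if all(l == 0 for l in lams):
            raise ValueError("at least one loss weight must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.normalized and not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must be in (0, 1] for normalized embeddings")


def project(h, W, pooling: str = "mean", normalize: bool = True) -> Tensor:
    """Pool a (B, T, D) representation over time and project: ``z = W h``.

    ``W`` has shape (P, D); the result is one embedding row of width P per
    sample, L2-normalized when ``normalize`` is set.
    """
    h = Tensor.as_tensor(h)
    if h.ndim == 2:
        h = h.reshape(1, *h.shape)
    if pooling == "mean":
        pooled = h.mean(axis=1)
    elif pooling == "last":
        pooled = h[:, -1, :]
    else:
        raise ValueError(f"unknown pooling {pooling!r}")
    W = Tensor.as_tensor(W)
    if W.shape[1] != pooled.shape[1]:
        raise ValueError(
            f"projection expects width {W.shape[1]}, got {pooled.shape[1]}")
    z = pooled @ W.transpose_last()
    return z.l2_normalize() if normalize else z


class ProjectionHead(Module):
    """Trainable bias-free projection into the shared embedding space."""

    def __init__(self, in_width: int, proj_width: int = 64, pooling: str = "mean",
                 normalize: bool = True, rng: np.random.Generator | None = None):
        self.linear = Linear(in_width, proj_width, bias=False, rng=rng)
        self.pooling = pooling
        self.normalize = normalize

    def forward(self, h) -> Tensor:
        return project(h, self.linear.weight.transpose_last(),
                       pooling=self.pooling, normalize=self.normalize)


@dataclass
class ContrastiveSet:
    """Anchor with its positive/negative embedding rows for one scheme."""

    anchor: np.ndarray
    positives: np.ndarray              # (n_pos, P)
    negatives: np.ndarray              # (n_neg, P)
    scheme: str
    anchor_modality: str
    anchor_index: int
    positive_tags: list = field(default_factory=list)
    negative_tags: list = field(default_factory=list)


def _present_mask(energy_flags, n):
    if energy_flags is None:
        return np.ones(n, dtype=bool)
    return np.array([f.is_present for f in energy_flags], dtype=bool)


def build_pairs(z_all: dict, labels, anchor_idx: int, anchor_modality: str,
                scheme: str, energy_flags=None):
    """Construct the contrastive set for one anchor, or None to skip it.

    ``z_all`` maps each modality to its (B, P) embedding array.  Audio
    embeddings of silent samples are removed before set construction in
    every scheme, and an anchor whose own audio is silent is skipped when
    the anchor modality is audio.  Returns ``None`` when no positive
    survives (the skip-anchor signal).
    """
    if scheme not in ("amcl", "emcl", "smcl"):
        raise ValueError(f"unknown scheme {scheme!r}")
    if anchor_modality not in MODALITIES:
        raise ValueError(f"unknown modality {anchor_modality!r}")
    labels = np.asarray(labels)
    z = {m: np.asarray(v.data if isinstance(v, Tensor) else v) for m, v in z_all.items()}
    n = labels.size
    present = _present_mask(energy_flags, n)
    i = anchor_idx
    if anchor_modality == "audio" and not present[i]:
        return None

    def ok(m, j):
        return present[j] if m == "audio" else True

    anchor = z[anchor_modality][i]
    if scheme == "amcl":
        m = anchor_modality
        pos_idx = [j for j in range(n) if j != i and labels[j] == labels[i] and ok(m, j)]
        neg_idx = [j for j in range(n) if labels[j] != labels[i] and ok(m, j)]
        if not pos_idx:
            return None
        return ContrastiveSet(anchor, z[m][pos_idx], z[m][neg_idx], scheme, m, i,
                              [(m, j) for j in pos_idx], [(m, j) for j in neg_idx])
    if scheme == "emcl":
        others = [m for m in MODALITIES if m != anchor_modality]
        pos, neg, ptags, ntags = [], [], [], []
        for m in others:
            for j in range(n):
                if not ok(m, j):
                    continue
                if labels[j] == labels[i]:
                    pos.append(z[m][j]); ptags.append((m, j))
                else:
                    neg.append(z[m][j]); ntags.append((m, j))
        if not pos:
            return None
        return ContrastiveSet(anchor, np.array(pos), np.array(neg) if neg
                              else np.empty((0, anchor.size)), scheme,
                              anchor_modality, i, ptags, ntags)
    # smcl: the anchor's own other-modality embeddings, audio-excluded
    others = [m for m in MODALITIES if m != anchor_modality]
    pos, ptags = [], []
    for m in others:
        if ok(m, i):
            pos.append(z[m][i]); ptags.append((m, i))
    if not pos:
        return None
    return ContrastiveSet(anchor, np.array(pos), np.empty((0, anchor.size)),
                          scheme, anchor_modality, i, ptags, [])


def _ratio_loss(pos_sims, neg_sims, weights: MerclWeights) -> float:
    pos_sims = np.asarray(pos_sims, dtype=np.float64).reshape(-1)
    neg_sims = np.asarray(neg_sims, dtype=np.float64).reshape(-1)
    if pos_sims.size == 0:
        raise ValueError("ratio loss requires at least one positive")
    if weights.literal_mode:
        num = pos_sims.sum()
        den = num + neg_sims.sum()
        if num <= 0 or den <= 0:
            raise LiteralDomainError(
                "raw inner-product ratio is nonpositive; use the softened "
                "mode (literal_mode=False) which maps similarities through "
                "exp(s / temperature)")
        return float(-np.log(num / den))
    t = weights.temperature
    num = np.exp(pos_sims / t).sum()
    den = num + np.exp(neg_sims / t).sum()
    return float(-np.log(num / den))


def amcl_loss(cset: ContrastiveSet, weights: MerclWeights | None = None) -> float:
    """Intra-modal ratio loss for one anchor's contrastive set."""
    weights = weights or MerclWeights()
    pos = cset.positives @ cset.anchor
    neg = cset.negatives @ cset.anchor if cset.negatives.size else np.empty(0)
    return _ratio_loss(pos, neg, weights)


def emcl_loss(cset: ContrastiveSet, weights: MerclWeights | None = None) -> float:
    """Inter-modal ratio loss; same functional form as the intra-modal loss."""
    return amcl_loss(cset, weights)


def smcl_loss(z_anchor, positives, alpha: float = 0.8) -> float:
    """Sample-wise alignment loss ``1/2 * sum_i (s_i - alpha)^2``.

    ``positives`` are the anchor sample's surviving other-modality
    embedding rows (two, or one after silent-audio exclusion) — or a
    vector of precomputed similarities.
    """
    positives = np.asarray(positives, dtype=np.float64)
    if positives.size == 0:
        raise ValueError("smcl_loss requires at least one surviving positive")
    if positives.ndim == 1 and z_anchor is None:
        sims = positives
    else:
        sims = np.atleast_2d(positives) @ np.asarray(z_anchor, dtype=np.float64)
    return float(0.5 * np.sum((sims - alpha) ** 2))


@dataclass
class MerclResult:
    total: Tensor
    amcl: float
    emcl: float
    smcl: float
    skipped: dict

    def breakdown(self) -> dict:
        return {"amcl": self.amcl, "emcl": self.emcl, "smcl": self.smcl,
                "total": self.total.item(), "skipped": dict(self.skipped)}


def _masked_mean(loss_vec: Tensor, valid: np.ndarray) -> Tensor:
    return (loss_vec * valid).sum() * (1.0 / max(valid.sum(), 1))


def _batched_ratio_term(S_list, pos_masks, neg_masks, anchor_ok, weights):
    """Vectorized ratio loss over all anchors of one (modality, scheme).

    ``S_list`` are similarity Tensors (B, B_k) against one or more candidate
    pools with matching boolean masks.  Returns (mean loss Tensor over valid
    anchors, number of valid anchors, number skipped).
    """
    n = anchor_ok.size
    pos_count = sum(m.sum(axis=1) for m in pos_masks)
    valid = (anchor_ok & (pos_count > 0)).astype(np.float64)
    inv = 1.0 - valid
    if weights.literal_mode:
        num = None
        den_neg = None
        for S, pm, nm in zip(S_list, pos_masks, neg_masks):
            p = (S * pm).sum(axis=1)
            q = (S * nm).sum(axis=1)
            num = p if num is None else num + p
            den_neg = q if den_neg is None else den_neg + q
        den = num + den_neg
        if np.any((num.data <= 0) & (valid > 0)) or np.any((den.data <= 0) & (valid > 0)):
            raise LiteralDomainError(
                "raw inner-product ratio is nonpositive for some anchor; "
                "use the softened mode (literal_mode=False)")
    else:
        t = weights.temperature
        num = None
        den_neg = None
        for S, pm, nm in zip(S_list, pos_masks, neg_masks):
            E = (S * (1.0 / t)).exp()
            p = (E * pm).sum(axis=1)
            q = (E * nm).sum(axis=1)
            num = p if num is None else num + p
            den_neg = q if den_neg is None else den_neg + q
        den = num + den_neg
    num_safe = num * valid + inv
    den_safe = den * valid + inv
    loss_vec = -(num_safe.log() - den_safe.log())
    n_valid = int(valid.sum())
    return _masked_mean(loss_vec, valid), n_valid, n - n_valid


def mercl_loss(z: dict, labels, energy_flags=None,
               weights: MerclWeights | None = None) -> MerclResult:
    """Combined contrastive objective over a mini-batch.

    ``z`` maps each modality to its (B, P) embedding Tensor.  Anchors
    iterate over every sample in every modality; each term is the mean over
    its valid anchors and over the three anchor-modality roles.  Returns the
    weighted total (differentiable) plus the unweighted term values and
    per-scheme skip counts.
    """
    weights = weights or MerclWeights()
    z = {m: Tensor.as_tensor(v) for m, v in z.items()}
    for m in MODALITIES:
        if m not in z:
            raise ValueError(f"missing modality {m!r} in embeddings")
    labels = np.asarray(labels)
    n = labels.size
    present = _present_mask(energy_flags, n)
    same = labels[:, None] == labels[None, :]
    eye = np.eye(n, dtype=bool)
    elem_ok = {m: (present if m == "audio" else np.ones(n, dtype=bool))
               for m in MODALITIES}

    skipped = {"amcl": 0, "emcl": 0, "smcl": 0}
    terms = {"amcl": [], "emcl": [], "smcl": []}

    for m in MODALITIES:
        a_ok = elem_ok[m]
        # ---- AMCL -----------------------------------------------------
        S = z[m] @ z[m].transpose_last()
        pm = (same & ~eye & elem_ok[m][None, :]).astype(np.float64)
        nm = (~same & elem_ok[m][None, :]).astype(np.float64)
        t_loss, n_valid, n_skip = _batched_ratio_term([S], [pm], [nm], a_ok, weights)
        skipped["amcl"] += n_skip
        if n_valid:
            terms["amcl"].append(t_loss)
        # ---- EMCL -----------------------------------------------------
        others = [o for o in MODALITIES if o != m]
        S_list, pms, nms = [], [], []
        for o in others:
            S_list.append(z[m] @ z[o].transpose_last())
            pms.append((same & elem_ok[o][None, :]).astype(np.float64))
            nms.append((~same & elem_ok[o][None, :]).astype(np.float64))
        t_loss, n_valid, n_skip = _batched_ratio_term(S_list, pms, nms, a_ok, weights)
        skipped["emcl"] += n_skip
        if n_valid:
            terms["emcl"].append(t_loss)
        # ---- SMCL -----------------------------------------------------
        pos_count = sum(elem_ok[o].astype(int) for o in others)
        valid = (a_ok & (pos_count > 0)).astype(np.float64)
        loss_vec = None
        for o in others:
            s = (z[m] * z[o]).sum(axis=1)
            contrib = ((s - weights.alpha) ** 2) * elem_ok[o].astype(np.float64)
            loss_vec = contrib if loss_vec is None else loss_vec + contrib
        loss_vec = loss_vec * 0.5
        n_valid = int(valid.sum())
        skipped["smcl"] += n - n_valid
        if n_valid:
            terms["smcl"].append(_masked_mean(loss_vec, valid))

    if not any(terms.values()):
        raise ValueError("every anchor was skipped; cannot compute MERCL loss")

    def term_mean(name):
        if not terms[name]:
            return Tensor(0.0)
        acc = terms[name][0]
        for t in terms[name][1:]:
            acc = acc + t
        return acc * (1.0 / len(terms[name]))

    t_amcl, t_emcl, t_smcl = term_mean("amcl"), term_mean("emcl"), term_mean("smcl")
    total = (t_amcl * weights.lambda_amcl + t_emcl * weights.lambda_emcl
             + t_smcl * weights.lambda_smcl)
    return MerclResult(total=total, amcl=t_amcl.item(), emcl=t_emcl.item(),
                       smcl=t_smcl.item(), skipped=skipped)
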
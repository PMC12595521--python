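"""Latent-space variant design: Gaussian sampling around the wildtype
embedding, argmax decoding, and Hamming-constrained acceptance.

Variants are proposed by sampling a diagonal Gaussian centered at the
wildtype's posterior mean (standard deviation = ``sigma_scale`` × the
posterior standard deviation), decoding each latent point to a single
sequence by per-position argmax, and rejecting any decoded sequence that
(a) differs from the wildtype at more than ``max_hamming`` columns,
(b) duplicates an already-accepted candidate or the wildtype itself, or
(c) was tested in a previous round. Every emitted variant therefore
satisfies the Hamming constraint by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from thermorca.curation import SequenceRecord, Source
from thermorca.encoding import encode_sequences, decode_argmax, hamming_matrix
from thermorca.vae import VaeModel, LatentPoint, embed, decoder_probabilities, predict_property

log = logging.getLogger(__name__)


class SamplerStarvedError(RuntimeError):
    """The rejection sampler hit its attempt cap before filling the request."""

    def __init__(self, accepted: int, requested: int, attempts: int):
        rate = accepted / attempts if attempts else 0.0
        super().__init__(
            f"sampler starved: accepted {accepted}/{requested} candidates after "
            f"{attempts} attempts (acceptance rate {rate:.4f})"
        )
        self.accepted = accepted
        self.requested = requested
        self.attempts = attempts
        self.acceptance_rate = rate


@dataclass
class DesignConstraints:
    """Constraints for one design round.

    ``max_hamming`` bounds the distance of any emitted variant to the
    wildtype (default 20 substitutions). ``sigma_scale`` scales the
    sampling Gaussian's standard deviation; ``sigma_units`` selects the
    base unit — ``"prior"`` (default) samples at sigma_scale·1 per latent
    dimension, the latent prior's natural scale, while ``"posterior"``
    uses sigma_scale·σ(x) from the wildtype's encoding (posteriors of a
    well-fit VAE are much tighter than the prior, so posterior units
    explore a far smaller neighborhood). ``exclusion_seqs`` holds
    previously tested sequences (the aligned strings themselves) so
    re-proposals are discarded. The default round size of 704 echoes the
    scale of a single screening round.
    """

    max_hamming: int = 20
    n_candidates: int = 704
    sigma_scale: float = 1.0
    sigma_units: str = "prior"
    exclusion_seqs: frozenset[str] = field(default_factory=frozenset)
    attempt_factor: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_hamming < 0:
            raise ValueError("max_hamming must be nonnegative")
        if self.n_candidates < 1:
            raise ValueError("n_candidates must be at least 1")
        if self.sigma_units not in ("prior", "posterior"):
            raise ValueError(f"unknown sigma_units {self.sigma_units!r}")

    def sampling_sd(self, center: "LatentPoint") -> np.ndarray:
        if self.sigma_units == "posterior":
            return self.sigma_scale * np.exp(0.5 * center.log_variance)
        return self.sigma_scale * np.ones_like(center.mean)


def sample_latent(center: LatentPoint, constraints: DesignConstraints, n: int | None = None) -> np.ndarray:
    """Draw latent vectors from a diagonal Gaussian centered at the
    posterior mean, with standard deviation per :meth:`DesignConstraints.sampling_sd`.

    Deterministic given ``constraints.seed``. As sigma_scale → 0 every draw
    equals μ.
    """
    if constraints.sigma_scale < 0:
        raise ValueError("sigma_scale must be nonnegative")
    rng = np.random.default_rng(constraints.seed)
    n = n if n is not None else constraints.n_candidates
    sd = constraints.sampling_sd(center)
    return center.mean + sd * rng.standard_normal((n, center.mean.size))


def propose_variants(
    model: VaeModel,
    wildtype: str,
    constraints: DesignConstraints,
    round_label: str = "design1",
    id_prefix: str = "syn",
    allow_partial: bool = False,
) -> list[SequenceRecord]:
    """Propose up to ``n_candidates`` distinct variants near the wildtype.

    Sampling proceeds in chunks until the request is filled or the attempt
    cap (``attempt_factor × n_candidates``) is reached, at which point a
    :class:`SamplerStarvedError` carries acceptance-rate diagnostics
    (``allow_partial=True`` instead returns the non-empty partial set).
    Returned records are SequenceRecords over aligned (gapped) strings with
    provenance ``synthetic`` and the given round label.
    """
    onehot = encode_sequences([wildtype], ["wt"])
    center = embed(model, onehot)[0]
    rng = np.random.default_rng(constraints.seed)
    sd = constraints.sampling_sd(center)

    cap = constraints.attempt_factor * constraints.n_candidates
    accepted: list[str] = []
    seen: set[str] = {wildtype} | set(constraints.exclusion_seqs)
    attempts = 0
    chunk = min(max(constraints.n_candidates, 256), 4096)
    while len(accepted) < constraints.n_candidates and attempts < cap:
        m = min(chunk, cap - attempts)
        z = center.mean + sd * rng.standard_normal((m, center.mean.size))
        probs = decoder_probabilities(model, z)
        seqs = decode_argmax(probs)
        dists = hamming_matrix(seqs, wildtype)
        attempts += m
        for seq, d in zip(seqs, dists):
            if d > constraints.max_hamming or seq in seen:
                continue
            seen.add(seq)
            accepted.append(seq)
            if len(accepted) == constraints.n_candidates:
                break
    if len(accepted) < constraints.n_candidates and not (allow_partial and accepted):
        raise SamplerStarvedError(len(accepted), constraints.n_candidates, attempts)
    log.info(
        "propose_variants: accepted %d/%d attempts (rate %.3f)",
        len(accepted), attempts, len(accepted) / attempts,
    )
    records = [
        SequenceRecord(
            id=f"{id_prefix}_{round_label}_{i:05d}",
            residues=seq.replace("-", "X"),  # unaligned view uses X for gap columns
            source=Source.SYNTHETIC,
            round=round_label,
        )
        for i, seq in enumerate(accepted)
    ]
    # keep the aligned string alongside; downstream stages work on alignments
    for rec, seq in zip(records, accepted):
        rec.aligned = seq  # type: ignore[attr-defined]
    return records


def design_round(
    model: VaeModel,
    wildtype: str,
    constraints: DesignConstraints,
    screen_history: list | None = None,
    round_label: str = "design1",
    oversample: int = 4,
) -> list[SequenceRecord]:
    """Propose and rank candidates for one design round.

    Oversamples ``oversample × n_candidates`` accepted variants, ranks them
    by predicted tmax from the semi-supervised head (descending; ties by
    fewer mutations to the wildtype, then lexical id), and returns the top
    ``n_candidates``. With an untrained-head (unsupervised) model the
    ranking degenerates to the mutation-count/lexical order.
    """
    history = screen_history or []
    if history and not model.has_property_head:
        raise ValueError("design with screening history requires a semi-supervised model")
    pool_constraints = replace(constraints, n_candidates=constraints.n_candidates * max(oversample, 1))
    pool = propose_variants(model, wildtype, pool_constraints, round_label=round_label, allow_partial=True)
    if len(pool) < constraints.n_candidates:
        raise SamplerStarvedError(
            len(pool), constraints.n_candidates, pool_constraints.attempt_factor * pool_constraints.n_candidates
        )
    aligned = [rec.aligned for rec in pool]  # type: ignore[attr-defined]
    dists = hamming_matrix(aligned, wildtype)
    if model.has_property_head:
        pred_tmax, _ = predict_property(model, encode_sequences(aligned, [r.id for r in pool]))
    else:
        pred_tmax = np.zeros(len(pool))
    order = sorted(
        range(len(pool)),
        key=lambda i: (-pred_tmax[i], int(dists[i]), pool[i].id),
    )
    chosen = []
    for rank, i in enumerate(order[: constraints.n_candidates]):
        rec = pool[i]
        rec.id = f"syn_{round_label}_{rank:05d}"
        rec.predicted_tmax = float(pred_tmax[i])  # type: ignore[attr-defined]
        rec.hamming_to_wt = int(dists[i])  # type: ignore[attr-defined]
        chosen.append(rec)
    return chosen


def candidates_manifest(records: list[SequenceRecord], model: VaeModel | None = None) -> pd.DataFrame:
    """CSV-ready manifest: id, round, hamming_to_wt, predicted_tmax, z1..zk."""
    rows = []
    coords = None
    if model is not None:
        pts = embed(model, encode_sequences([r.aligned for r in records], [r.id for r in records]))  # type: ignore[attr-defined]
        coords = [p.mean for p in pts]
    for i, rec in enumerate(records):
        row = {
            "id": rec.id,
            "round": rec.round,
            "hamming_to_wt": getattr(rec, "hamming_to_wt", None),
            "predicted_tmax": getattr(rec, "predicted_tmax", None),
        }
        if coords is not None:
            row.update({f"z{k + 1}": float(coords[i][k]) for k in range(coords[i].size)})
        rows.append(row)
    return pd.DataFrame(rows)
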
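"""Synthetic study-condition generator.

Everything downstream of data collection is testable against this module:
it produces an ortholog-like MSA containing a designated wildtype, a planted
genotype→phenotype map (a few key alignment columns whose stabilizing
residue raises the maximum tolerated heat-shock temperature, at a cost in
catalytic rate — the classic stability–activity trade-off), and noisy A340
decay traces whose initial slope is proportional to residual ATPase
activity after a heat shock.

The phenotype map is a pure function of genotype:

- ``tmax`` = ``base_tmax`` + ``delta_tmax`` per key position carrying its
  stabilizing residue (mimicking a single stabilizing substitution such as
  the proline→glycine swap of the best screened variant);
- ATPase rate is scaled by ``activity_scale`` per stabilizing substitution;
- a sequence is inactive outright (even at room temperature) if it carries
  a non-wildtype residue at any *fragile* column — this emulates the large
  fraction of natural orthologs that show no activity in the screen.

Traces follow a linear-then-plateau decay: A340(t) = A0 − r·t clipped at a
floor (substrate exhaustion), r proportional to residual activity, with the
screen's permissive long endpoint in mind. Heat shock acts as a step
function of tmax: full activity at or below tmax, none above.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from thermorca.curation import AlignedSet
from thermorca.encoding import hamming
from thermorca.screening import AssayTrace, RT

_AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: heat-shock challenge ladder (°C); room temperature is assayed separately
DEFAULT_LADDER: tuple[float, ...] = (38.0, 42.0, 46.0, 50.0)


@dataclass(frozen=True)
class GroundTruth:
    """Planted genotype→phenotype map for a synthetic campaign.

    Parameters
    ----------
    width : alignment width the map applies to.
    wildtype_row : the aligned wildtype sequence.
    key_positions : 0-based alignment columns carrying the thermotolerance
        determinant; distinct and non-gap in the wildtype.
    stabilizing : mapping key position → stabilizing residue.
    fragile_positions : 0-based columns where any deviation from the
        wildtype residue abolishes activity.
    base_tmax : °C tolerated by the wildtype (default 38 — active after a
        38 °C shock, inactivated at 42 °C and above).
    delta_tmax : °C gained per stabilizing substitution (default 8).
    activity_scale : multiplicative ATPase-rate factor per stabilizing
        substitution, in (0, 1]; < 1 encodes the stability–activity
        trade-off.
    trace_noise_sd : Gaussian observation noise on A340, absorbance units.
    ladder : heat-shock challenge temperatures (°C).
    """

    width: int
    wildtype_row: str
    key_positions: tuple[int, ...]
    stabilizing: dict[int, str]
    fragile_positions: tuple[int, ...] = ()
    base_tmax: float = 38.0
    delta_tmax: float = 8.0
    activity_scale: float = 0.3
    trace_noise_sd: float = 0.005
    ladder: tuple[float, ...] = DEFAULT_LADDER
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.wildtype_row) != self.width:
            raise ValueError("wildtype_row length must equal width")
        if len(set(self.key_positions)) != len(self.key_positions):
            raise ValueError("key_positions must be distinct")
        for p in self.key_positions:
            if not 0 <= p < self.width:
                raise ValueError(f"key position {p} outside alignment width {self.width}")
            if self.wildtype_row[p] == "-":
                raise ValueError(f"key position {p} is a gap in the wildtype row")
            if p not in self.stabilizing:
                raise ValueError(f"key position {p} lacks a stabilizing residue")
        if not 0.0 < self.activity_scale <= 1.0:
            raise ValueError("activity_scale must be in (0, 1]")
        lo, hi = min(self.ladder), max(self.ladder)
        reachable = any(
            lo <= self.base_tmax + k * self.delta_tmax <= hi
            for k in range(1, len(self.key_positions) + 1)
        )
        if not (lo <= self.base_tmax <= hi) or not reachable:
            raise ValueError("base_tmax and at least one stabilized tmax must lie inside the ladder")


def _check_width(seq: str, truth: GroundTruth) -> None:
    if len(seq) != truth.width:
        raise ValueError(f"sequence width {len(seq)} does not match ground truth width {truth.width}")


def n_stabilizing(seq: str, truth: GroundTruth) -> int:
    """Number of key positions at which ``seq`` carries the stabilizing residue."""
    _check_width(seq, truth)
    return sum(seq[p] == truth.stabilizing[p] for p in truth.key_positions)


def true_tmax(seq: str, truth: GroundTruth) -> float:
    """Planted maximum tolerated heat-shock temperature: additive in the
    number of stabilizing substitutions. Pure function of genotype."""
    return truth.base_tmax + n_stabilizing(seq, truth) * truth.delta_tmax


def is_functional(seq: str, truth: GroundTruth) -> bool:
    """True unless the sequence deviates from the wildtype at a fragile column."""
    _check_width(seq, truth)
    return all(seq[p] == truth.wildtype_row[p] for p in truth.fragile_positions)


def true_rate(seq: str, shock_temp: float | str, truth: GroundTruth, base_rate: float = 0.02) -> float:
    """Noise-free initial A340 decay rate (ΔA340/min, positive magnitude).

    Zero if the sequence is non-functional or the shock exceeds its tmax;
    otherwise ``base_rate`` scaled by ``activity_scale`` per stabilizing
    substitution (the trade-off).
    """
    if not is_functional(seq, truth):
        return 0.0
    if shock_temp != RT and float(shock_temp) > true_tmax(seq, truth):
        return 0.0
    return base_rate * truth.activity_scale ** n_stabilizing(seq, truth)


# ---------------------------------------------------------------------------
# MSA generation


def generate_msa(
    n_seqs: int,
    length: int,
    conservation: float | np.ndarray = 0.9,
    seed: int = 0,
    wildtype_id: str = "WT",
    wildtype_row: str | None = None,
    alternates: dict[int, str] | None = None,
    n_factors: int = 2,
    flip_noise: float = 0.02,
) -> AlignedSet:
    """Sample an ortholog-like MSA around a wildtype.

    ``conservation`` gives, per column (scalar broadcasts), the marginal
    probability that a row carries the wildtype residue there; the
    complement is spread uniformly over that column's alternate residues
    (3 per column by default, overridable via ``alternates``).

    Variation is *correlated across columns* through a latent-factor model,
    the minimal structure that makes an MSA informative for a latent-variable
    sequence model: each row draws a standard-Gaussian factor vector
    u ∈ R^``n_factors``, and column j deviates from the wildtype when
    u·a_j exceeds a threshold set so the marginal conservation is honored
    (a_j is a fixed random unit loading per column). An independent
    ``flip_noise`` per cell adds residual idiosyncratic variation. Rows are
    therefore exchangeable, column marginals follow the profile, and
    pairwise column states between rows are independent — but within a row,
    deviations co-occur along the factor directions, the way correlated
    substitutions co-occur in related orthologs. Row 0 is the exact
    wildtype (u = 0). Deterministic given ``seed``.
    """
    if n_seqs < 2:
        raise ValueError("n_seqs must be at least 2")
    if length < 10:
        raise ValueError("length must be at least 10")
    if not 0.0 <= flip_noise < 0.5:
        raise ValueError("flip_noise must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    p = np.broadcast_to(np.asarray(conservation, dtype=float), (length,)).copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("conservation probabilities must lie in [0, 1]")
    if wildtype_row is None:
        wildtype_row = "".join(rng.choice(list(_AA20), size=length))
    elif len(wildtype_row) != length:
        raise ValueError("wildtype_row length must equal `length`")
    alt_cols: list[str] = []
    for j in range(length):
        if alternates and j in alternates:
            alt = alternates[j]
        else:
            pool = [a for a in _AA20 if a != wildtype_row[j]]
            alt = "".join(rng.choice(pool, size=3, replace=False))
        alt_cols.append(alt)

    # column loadings and thresholds: u·a_j ~ N(0,1), so a threshold of
    # Phi^{-1}(q_j) gives a factor-driven deviation probability of 1-q_j;
    # the flip noise is folded in so the marginal stays 1-p_j.
    from scipy.stats import norm

    loadings = rng.standard_normal((length, n_factors))
    loadings /= np.linalg.norm(loadings, axis=1, keepdims=True)
    p_alt = 1.0 - p
    q_factor = np.clip((p_alt - flip_noise) / (1.0 - 2.0 * flip_noise), 0.0, 1.0)
    thresholds = norm.ppf(1.0 - q_factor)

    u = rng.standard_normal((n_seqs - 1, n_factors))
    factor_dev = (u @ loadings.T) > thresholds  # (n_seqs-1, length)
    noise_flip = rng.random((n_seqs - 1, length)) < flip_noise
    deviates = factor_dev ^ noise_flip
    alt_choice = rng.integers(0, 3, size=(n_seqs - 1, length))

    ids = [wildtype_id] + [f"nat{i:04d}" for i in range(1, n_seqs)]
    rows = [wildtype_row]
    for i in range(n_seqs - 1):
        chars = []
        for j in range(length):
            if deviates[i, j]:
                alt = alt_cols[j]
                chars.append(alt[alt_choice[i, j] % len(alt)])
            else:
                chars.append(wildtype_row[j])
        rows.append("".join(chars))
    return AlignedSet(ids=ids, rows=rows, wildtype_id=wildtype_id)


def expected_pairwise_identity(conservation: float | np.ndarray, length: int, n_alternates: int = 3) -> float:
    """Analytic expected pairwise identity of :func:`generate_msa` output.

    Per column with wildtype probability p and m equiprobable alternates,
    two independent rows match with probability p² + (1−p)²/m; the mean
    identity is the average over columns.
    """
    p = np.broadcast_to(np.asarray(conservation, dtype=float), (length,))
    return float(np.mean(p**2 + (1 - p) ** 2 / n_alternates))


def make_planted_dataset(
    n_seqs: int = 200,
    length: int = 120,
    conservation: float = 0.9,
    n_key: int = 1,
    key_conservation: float = 0.8,
    n_fragile: int = 10,
    fragile_conservation: float = 0.97,
    seed: int = 0,
    **truth_kwargs,
) -> tuple[AlignedSet, GroundTruth]:
    """Generate an MSA together with its planted phenotype map.

    Key columns carry proline in the wildtype and glycine as the sole
    (stabilizing) alternate, seen in ``1 − key_conservation`` of natural
    rows. Fragile columns are highly conserved (any deviation kills
    activity, so purifying selection would keep them near-fixed); with the
    defaults roughly a quarter of natural rows are inactive at room
    temperature. Key, fragile and background columns are disjoint.
    """
    rng = np.random.default_rng(seed)
    cols = rng.permutation(length)
    key_positions = tuple(int(c) for c in np.sort(cols[:n_key]))
    fragile_positions = tuple(int(c) for c in np.sort(cols[n_key : n_key + n_fragile]))
    wildtype_row = "".join(rng.choice(list(_AA20), size=length))
    wt = list(wildtype_row)
    for p in key_positions:
        wt[p] = "P"
    wildtype_row = "".join(wt)
    p_cols = np.full(length, conservation)
    for p in key_positions:
        p_cols[p] = key_conservation
    for p in fragile_positions:
        p_cols[p] = fragile_conservation
    alternates = {p: "G" for p in key_positions}
    msa = generate_msa(
        n_seqs,
        length,
        conservation=p_cols,
        seed=int(rng.integers(2**31 - 1)),
        wildtype_row=wildtype_row,
        alternates=alternates,
    )
    truth = GroundTruth(
        width=length,
        wildtype_row=wildtype_row,
        key_positions=key_positions,
        stabilizing={p: "G" for p in key_positions},
        fragile_positions=fragile_positions,
        seed=seed,
        **truth_kwargs,
    )
    return msa, truth


# ---------------------------------------------------------------------------
# assay-trace simulation


def simulate_trace(
    seq: str,
    shock_temp: float | str,
    truth: GroundTruth,
    duration: float = 60.0,
    n_points: int = 61,
    seed: int = 0,
    a0: float = 1.0,
    floor: float = 0.05,
    base_rate: float = 0.02,
    sequence_id: str = "seq",
    well_id: str | None = None,
) -> AssayTrace:
    """Simulate one well's A340 trace after a heat shock.

    Linear decay at the planted rate, clipped at ``floor`` (substrate
    exhaustion), plus Gaussian observation noise of sd
    ``truth.trace_noise_sd``. Flat in expectation when the shock exceeds the
    sequence's tmax or the sequence is non-functional. Deterministic given
    ``seed``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if n_points < 3:
        raise ValueError("n_points must be at least 3")
    rate = true_rate(seq, shock_temp, truth, base_rate=base_rate)
    times = np.linspace(0.0, duration, n_points)
    clean = np.maximum(a0 - rate * times, floor)
    rng = np.random.default_rng(seed)
    noisy = clean + rng.normal(0.0, truth.trace_noise_sd, size=n_points)
    return AssayTrace(
        well_id=well_id or f"{sequence_id}@{shock_temp}",
        sequence_id=sequence_id,
        shock_temp=shock_temp,
        concentration=5.0,
        times=times,
        a340=noisy,
    )


def simulate_screen(
    ids: list[str],
    rows: list[str],
    truth: GroundTruth,
    seed: int = 0,
    duration: float = 60.0,
    n_points: int = 61,
    include_controls: bool = True,
) -> list[AssayTrace]:
    """Simulate a full screening plate: every sequence at RT and at each
    ladder temperature, plus a no-enzyme blank and a wildtype positive
    control at RT.

    Per-well seeds are drawn from a generator seeded with ``seed``, so the
    plate is reproducible as a whole.
    """
    rng = np.random.default_rng(seed)
    conditions: list[float | str] = [RT, *truth.ladder]
    traces: list[AssayTrace] = []
    if include_controls:
        blank_times = np.linspace(0.0, duration, n_points)
        blank = np.full(n_points, 1.0) + rng.normal(0.0, truth.trace_noise_sd, size=n_points)
        traces.append(
            AssayTrace(
                well_id="blank@RT", sequence_id="__blank__", shock_temp=RT,
                concentration=0.0, times=blank_times, a340=blank, role="blank",
            )
        )
        pos = simulate_trace(
            truth.wildtype_row, RT, truth, duration, n_points,
            seed=int(rng.integers(2**31 - 1)), sequence_id="__positive__", well_id="pos@RT",
        )
        pos.role = "positive"
        traces.append(pos)
    for seq_id, row in zip(ids, rows):
        for cond in conditions:
            traces.append(
                simulate_trace(
                    row, cond, truth, duration, n_points,
                    seed=int(rng.integers(2**31 - 1)),
                    sequence_id=seq_id,
                )
            )
    return traces


def deposited_table(msa: AlignedSet, truth: GroundTruth, rounds: dict[str, str] | None = None) -> pd.DataFrame:
    """Build a synthetic stand-in for a deposited screen-results table
    (columns: id, sequence, round, active, max_temp) from the planted truth.

    ``rounds`` optionally maps sequence id → round label (default: every
    row "natural").
    """
    rows = []
    for seq_id, row in zip(msa.ids, msa.rows):
        active = is_functional(row, truth)
        if not active:
            max_temp = "inactive"
        else:
            tm = true_tmax(row, truth)
            max_temp = tm if tm >= min(truth.ladder) else "RT"
        rows.append(
            {
                "id": seq_id,
                "sequence": row,
                "round": (rounds or {}).get(seq_id, "natural"),
                "active": bool(active),
                "max_temp": max_temp,
            }
        )
    return pd.DataFrame(rows)


def write_trace_csv(traces: list[AssayTrace], path: str | Path) -> None:
    """Long-format trace CSV: well_id, sequence_id, shock_temp_C, time_min, a340."""
    frames = []
    for t in traces:
        frames.append(
            pd.DataFrame(
                {
                    "well_id": t.well_id,
                    "sequence_id": t.sequence_id,
                    "shock_temp_C": str(t.shock_temp),
                    "role": t.role,
                    "time_min": t.times,
                    "a340": t.a340,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trace_csv(path: str | Path) -> list[AssayTrace]:
    df = pd.read_csv(path)
    if "role" not in df.columns:
        df["role"] = "sample"
    traces = []
    for (well, seq_id, shock, role), grp in df.groupby(
        ["well_id", "sequence_id", "shock_temp_C", "role"], sort=False
    ):
        shock_val: float | str = RT if str(shock) == RT else float(shock)
        grp = grp.sort_values("time_min")
        traces.append(
            AssayTrace(
                well_id=str(well),
                sequence_id=str(seq_id),
                shock_temp=shock_val,
                concentration=5.0,
                times=grp["time_min"].to_numpy(),
                a340=grp["a340"].to_numpy(),
                role=str(role),
            )
        )
    return traces
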
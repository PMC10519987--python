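"""Contact-type composition, randomized backgrounds and enrichment ratios.

Observed contact-type fractions are normalized by the fraction expected
under a randomized sequence background.  Two realizations of the
background are provided and must agree: the analytic composition product
(2·f_a·f_b for a≠b, f_a² for a=a) and an explicit label-permutation test
(:func:`shuffle_background`).

Contact *events* are pair×frame occurrences: a pair in contact for many
frames contributes proportionally to the pool of all contacts seen in the
trajectory.  A unique-pair counting mode is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .contacts import ContactTable
from .model import Topology, ValidationError
from .sequence import CONSENSUS_HEPTAD, HeptadAnnotation

__all__ = [
    "composition",
    "expected_pair_fraction",
    "contact_type_fractions",
    "enrichment_table",
    "heptad_position_matrix",
    "shuffle_background",
    "HeptadMatrix",
]

TypePair = tuple[str, str]


def _pair(a: str, b: str) -> TypePair:
    return (a, b) if a <= b else (b, a)


def composition(
    sequences: Sequence[str],
    restrict: Optional[Sequence[np.ndarray]] = None,
) -> dict[str, float]:
    """Residue-type frequencies over the pooled sequences.

    ``restrict`` masks residues (e.g. canonical heptad residues only);
    frequencies always sum to 1 over the retained residues.
    """
    if not sequences:
        raise ValidationError("no sequences given")
    letters: list[str] = []
    for si, seq in enumerate(sequences):
        mask = None if restrict is None else np.asarray(restrict[si], dtype=bool)
        for i, ch in enumerate(seq):
            if mask is None or mask[i]:
                letters.append(ch)
    if not letters:
        raise ValidationError("no residues left after mask")
    values, counts = np.unique(letters, return_counts=True)
    total = counts.sum()
    return {str(v): c / total for v, c in zip(values, counts)}


def expected_pair_fraction(profile: dict[str, float], a: str, b: str) -> float:
    """Expected contact fraction of type pair (a, b) under random mixing."""
    for t in (a, b):
        if t not in profile:
            raise ValidationError(f"type {t!r} not in composition profile")
    if a == b:
        return profile[a] ** 2
    return 2.0 * profile[a] * profile[b]


def _event_weights(
    table: ContactTable, topology: Topology, mode: Literal["events", "unique"]
) -> dict[TypePair, float]:
    if not table.counts:
        raise ValidationError("empty contact table")
    weights: dict[TypePair, float] = {}
    for key, count in table.counts.items():
        ta = topology.residue(key.chain_a, key.res_a).name1
        tb = topology.residue(key.chain_b, key.res_b).name1
        w = count if mode == "events" else 1
        pair = _pair(ta, tb)
        weights[pair] = weights.get(pair, 0.0) + w
    return weights


def contact_type_fractions(
    table: ContactTable,
    topology: Topology,
    mode: Literal["events", "unique"] = "events",
    top_k: int = 10,
) -> tuple[dict[TypePair, float], pd.DataFrame]:
    """Observed contact-type fractions plus a descending top-k listing.

    Ties in the listing are broken lexicographically by pair name.
    """
    weights = _event_weights(table, topology, mode)
    total = sum(weights.values())
    fractions = {p: w / total for p, w in weights.items()}
    order = sorted(fractions.items(), key=lambda kv: (-kv[1], kv[0]))
    listing = pd.DataFrame(
        [
            {"rank": r + 1, "type_a": p[0], "type_b": p[1], "fraction": f}
            for r, (p, f) in enumerate(order[:top_k])
        ],
        columns=["rank", "type_a", "type_b", "fraction"],
    )
    return fractions, listing


def enrichment_table(
    observed: dict[TypePair, float], profile: dict[str, float]
) -> pd.DataFrame:
    """Observed/expected ratio per unordered type pair.

    Pairs with zero expected fraction get a missing ratio (NaN), never ∞.
    Pairs never observed but possible under the profile appear with
    observed 0.
    """
    types = sorted(profile)
    rows = []
    for a, b in combinations_with_replacement(types, 2):
        pair = _pair(a, b)
        exp = expected_pair_fraction(profile, a, b)
        obs = observed.get(pair, 0.0)
        ratio = obs / exp if exp > 0 else np.nan
        rows.append(
            {"type_a": pair[0], "type_b": pair[1], "observed": obs,
             "expected": exp, "ratio": ratio}
        )
    return pd.DataFrame(rows, columns=["type_a", "type_b", "observed", "expected", "ratio"])


def enrichment_with_se(
    table: ContactTable, topology: Topology, profile: dict[str, float],
    block_frames: int = 5,
) -> pd.DataFrame:
    """Enrichment ratios with batch-means standard errors.

    Consecutive analyzed frames are aggregated into blocks of
    ``block_frames`` and the observed type-pair fraction is computed per
    block; the ratio SE is the standard error of the mean block fraction
    divided by the analytic expected fraction.  Blocking tames both frame
    autocorrelation and the heavy skew of single-frame fractions for rare
    type pairs (a frame holds only a handful of contact events).  Blocks
    without contacts are skipped.
    """
    if not table.per_frame:
        raise ValidationError("ContactTable lacks per-frame contact sets")
    if block_frames < 1:
        raise ValidationError("block_frames must be >= 1")
    types = sorted(profile)
    pairs = [_pair(a, b) for a, b in combinations_with_replacement(types, 2)]
    col = {p: i for i, p in enumerate(pairs)}
    per_block_frac = []
    for start in range(0, len(table.per_frame), block_frames):
        row = np.zeros(len(pairs))
        for fset in table.per_frame[start:start + block_frames]:
            for key in fset:
                ta = topology.residue(key.chain_a, key.res_a).name1
                tb = topology.residue(key.chain_b, key.res_b).name1
                row[col[_pair(ta, tb)]] += 1
        if row.sum() > 0:
            per_block_frac.append(row / row.sum())
    if not per_block_frac:
        raise ValidationError("no frames with contacts")
    mat = np.asarray(per_block_frac)
    mean = mat.mean(axis=0)
    se = mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0]) if mat.shape[0] > 1 else np.full(len(pairs), np.nan)
    rows = []
    for p in pairs:
        exp = expected_pair_fraction(profile, *p)
        i = col[p]
        rows.append(
            {"type_a": p[0], "type_b": p[1],
             "observed": mean[i], "expected": exp,
             "ratio": mean[i] / exp if exp > 0 else np.nan,
             "ratio_se": se[i] / exp if exp > 0 else np.nan,
             "n_blocks": mat.shape[0]}
        )
    return pd.DataFrame(rows, columns=["type_a", "type_b", "observed", "expected",
                                       "ratio", "ratio_se", "n_blocks"])


@dataclass
class HeptadMatrix:
    """7×7 symmetric enrichment-ratio matrix over canonical heptad positions."""

    ratios: np.ndarray          # (7, 7), NaN where expected is zero
    observed: np.ndarray        # observed fraction per position pair
    expected: np.ndarray
    scope: str

    def to_dataframe(self) -> pd.DataFrame:
        labels = [f"pos{i}" for i in range(1, 8)]
        return pd.DataFrame(self.ratios, index=labels, columns=labels)


def heptad_position_matrix(
    table: ContactTable,
    topology: Topology,
    annotation: HeptadAnnotation,
    background: Literal["position", "residue"] = "position",
) -> HeptadMatrix:
    """Position-resolved interaction matrix over canonical heptad residues.

    Only residues whose identity matches the consensus at their heptad
    position contribute.  The default background uses the canonical
    position frequencies (equal in a pure repeat: expected 2/49
    off-diagonal, 1/49 on the diagonal); the ``residue`` background
    spreads residue-type frequencies evenly over the positions carrying
    each type.
    """
    if not topology.single_species():
        raise ValidationError("heptad matrix requires a single species")
    length = len(annotation)
    if len(topology.chains[0].residues) != length:
        raise ValidationError("annotation length does not match chain length")
    if not annotation.canonical.any():
        raise ValidationError("no canonical residues in annotation")

    pos_of = {
        c.chain_id: {r.index: k for k, r in enumerate(c.residues)}
        for c in topology.chains
    }
    obs_counts = np.zeros((7, 7))  # unordered counts kept in the upper triangle
    for key, count in table.counts.items():
        ka = pos_of[key.chain_a][key.res_a]
        kb = pos_of[key.chain_b][key.res_b]
        if not (annotation.canonical[ka] and annotation.canonical[kb]):
            continue
        pa = annotation.heptad_position[ka] - 1
        pb = annotation.heptad_position[kb] - 1
        obs_counts[min(pa, pb), max(pa, pb)] += count
    total = obs_counts.sum()
    if total == 0:
        raise ValidationError("no contacts between canonical residues")
    observed = np.zeros((7, 7))
    for p in range(7):
        for q in range(p, 7):
            observed[p, q] = observed[q, p] = obs_counts[p, q] / total

    canon_pos = annotation.heptad_position[annotation.canonical]
    if background == "position":
        f = np.bincount(canon_pos - 1, minlength=7) / canon_pos.size
    elif background == "residue":
        types = np.array(list(CONSENSUS_HEPTAD))
        canon_types = np.array(list(annotation.sequence))[annotation.canonical]
        f = np.zeros(7)
        for p in range(7):
            t = types[p]
            n_pos = int((types == t).sum())
            f[p] = (canon_types == t).mean() / n_pos
    else:
        raise ValidationError(f"unknown background {background!r}")
    expected = np.zeros((7, 7))
    for p in range(7):
        for q in range(7):
            expected[p, q] = f[p] * f[q] * (2.0 if p != q else 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(expected > 0, observed / expected, np.nan)
    return HeptadMatrix(ratios=ratios, observed=observed, expected=expected, scope=table.scope)


def shuffle_background(
    table: ContactTable,
    topology: Topology,
    n_shuffles: int = 1000,
    seed: int = 0,
    mode: Literal["events", "unique"] = "events",
) -> pd.DataFrame:
    """Empirical expected type-pair fractions from residue-label permutation.

    Residue type labels are permuted uniformly at random over all residues
    (composition preserved exactly); contact events keep their geometry and
    are re-typed.  Returns per type pair the mean fraction over shuffles
    and its standard error.
    """
    if n_shuffles < 1:
        raise ValidationError("n_shuffles must be >= 1")
    if not table.counts:
        raise ValidationError("empty contact table")
    rng = np.random.default_rng(seed)
    labels = topology.residue_name1.copy()
    n_res = labels.size
    flat = {
        key: (
            topology.flat_residue_id(key.chain_a, key.res_a),
            topology.flat_residue_id(key.chain_b, key.res_b),
        )
        for key in table.counts
    }
    keys = list(table.counts)
    ia = np.array([flat[k][0] for k in keys])
    ib = np.array([flat[k][1] for k in keys])
    w = np.array(
        [table.counts[k] if mode == "events" else 1 for k in keys], dtype=float
    )
    total = w.sum()

    sums: dict[TypePair, np.ndarray] = {}
    for s in range(n_shuffles):
        perm = rng.permutation(n_res)
        la = labels[perm[ia]]
        lb = labels[perm[ib]]
        frac: dict[TypePair, float] = {}
        for a, b, wt in zip(la, lb, w):
            p = _pair(str(a), str(b))
            frac[p] = frac.get(p, 0.0) + wt
        for p, v in frac.items():
            if p not in sums:
                sums[p] = np.zeros(n_shuffles)
            sums[p][s] = v / total
    rows = []
    for p in sorted(sums):
        vals = sums[p]
        rows.append(
            {
                "type_a": p[0],
                "type_b": p[1],
                "mean_fraction": vals.mean(),
                "se": vals.std(ddof=1) / np.sqrt(n_shuffles) if n_shuffles > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=["type_a", "type_b", "mean_fraction", "se"])
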
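"""Chromosome painting: haplotype-copying palettes under a Li-Stephens HMM.

Each recipient haplotype is modelled as an imperfect mosaic of the donor
haplotypes in a panel.  The hidden state is the donor currently being
copied; between adjacent sites at genetic distance ``g`` cM the chain
stays on its donor with probability ``exp(-n*g)`` and otherwise jumps to
a uniformly chosen donor (the standard uniform-prior simplification of the
Li-Stephens transition), and the emission probability is ``1-M`` on an
allele match and ``M`` on a mismatch.  Forward-backward posteriors are
aggregated into

* the expected genome fraction copied from each donor (posteriors weighted
  by half the flanking inter-site genetic intervals), and
* the expected number of chunks: entries into each donor's state plus the
  initial-state indicator, per chromosome.

The unlinked model treats sites independently (posterior proportional to
the emission alone) and reports expected matching counts.

``paint_all`` paints every individual against all others (the recipient's
own haplotypes are excluded from the panel by default) and aggregates
donor haplotypes by group label into an N x P palette matrix.

Note that linked-mode palettes depend on site order through the genetic
map; unlinked-mode palettes are invariant to site order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PaintingParams",
    "DonorPanel",
    "PaletteMatrix",
    "paint_linked",
    "paint_unlinked",
    "paint_all",
    "paint_dataset",
]


@dataclass(frozen=True)
class PaintingParams:
    """Copying-model parameters.

    mutation_rate
        Emission mismatch probability M in (0, 0.5).
    switch_rate
        Donor switch rate n per cM (> 0); only used in linked mode.
    mode
        "linked" (haplotype copying HMM) or "unlinked" (allele matching).
    self_exclusion
        "individual" removes both of the recipient's haplotypes from the
        panel; "haplotype" removes only the haplotype being painted.
    """

    mutation_rate: float = 0.01
    switch_rate: float = 1.0
    mode: str = "linked"
    self_exclusion: str = "individual"

    def __post_init__(self) -> None:
        if not (0.0 < self.mutation_rate < 0.5):
            raise ValueError(f"mutation_rate must be in (0, 0.5), got {self.mutation_rate}")
        if self.switch_rate <= 0:
            raise ValueError(f"switch_rate must be > 0, got {self.switch_rate}")
        if self.mode not in ("linked", "unlinked"):
            raise ValueError(f"mode must be 'linked' or 'unlinked', got {self.mode!r}")
        if self.self_exclusion not in ("individual", "haplotype"):
            raise ValueError(f"self_exclusion must be 'individual' or 'haplotype'")


@dataclass
class DonorPanel:
    """Donor haplotypes with ownership and group metadata."""

    haplotypes: np.ndarray          # (D, L) 0/1
    owner_ids: list[str]            # individual owning each haplotype
    group_labels: list[str]         # donor group per haplotype
    genetic_pos: np.ndarray         # (L,) cM within chromosome
    chrom: np.ndarray | None = None  # (L,) chromosome index; single chrom if None

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.genetic_pos = np.asarray(self.genetic_pos, dtype=float)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be a (D, L) matrix")
        D, L = self.haplotypes.shape
        if D == 0:
            raise ValueError("donor panel is empty")
        if len(self.owner_ids) != D or len(self.group_labels) != D:
            raise ValueError("owner_ids/group_labels must match haplotype count")
        if len(self.genetic_pos) != L:
            raise ValueError("genetic_pos length must match site count")
        if self.chrom is None:
            self.chrom = np.ones(L, dtype=np.int64)
        self.chrom = np.asarray(self.chrom, dtype=np.int64)
        for c in np.unique(self.chrom):
            if np.any(np.diff(self.genetic_pos[self.chrom == c]) <= 0):
                raise ValueError(f"genetic positions not strictly increasing on chrom {c}")

    @property
    def n_donors(self) -> int:
        return self.haplotypes.shape[0]


@dataclass
class PaletteMatrix:
    """N x P copying palette: recipients by donor groups.

    ``payload`` records what the entries are: "genome_fraction" rows sum
    to 1; "chunk_count" rows are expected matching/chunk counts and can be
    row-normalized on demand.
    """

    values: np.ndarray
    recipient_ids: list[str]
    donor_groups: list[str]
    payload: str = "genome_fraction"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, p = self.values.shape
        if n != len(self.recipient_ids) or p != len(self.donor_groups):
            raise ValueError("palette shape does not match ids/groups")
        if np.any(self.values < -1e-12):
            raise ValueError("palette entries must be non-negative")
        if self.payload not in ("genome_fraction", "chunk_count"):
            raise ValueError(f"unknown payload {self.payload!r}")
        if self.payload == "genome_fraction" and n:
            sums = self.values.sum(axis=1)
            if np.max(np.abs(sums - 1.0)) > 1e-9:
                raise ValueError("genome_fraction palette rows must sum to 1")

    def normalized(self) -> "PaletteMatrix":
        """Row-normalized copy (payload becomes genome_fraction-like weights)."""
        sums = self.values.sum(axis=1, keepdims=True)
        if np.any(sums <= 0):
            raise ValueError("cannot normalize rows with non-positive sums")
        return PaletteMatrix(self.values / sums, list(self.recipient_ids),
                             list(self.donor_groups), payload="genome_fraction")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.recipient_ids,
                            columns=self.donor_groups)


# ---------------------------------------------------------------------------
# per-haplotype painting
# ---------------------------------------------------------------------------

def _site_weights(gpos: np.ndarray) -> np.ndarray:
    """Trapezoid site weights: half the flanking inter-site intervals."""
    L = len(gpos)
    if L == 1:
        return np.ones(1)
    d = np.diff(gpos)
    w = np.zeros(L)
    w[:-1] += d / 2.0
    w[1:] += d / 2.0
    return w


def _forward_backward(hap: np.ndarray, donors: np.ndarray, gpos: np.ndarray,
                      M: float, n_rate: float):
    """Scaled forward-backward for one chromosome.

    Returns (posteriors (L, D), expected entries-into-state (D,) including
    the initial-state indicator).
    """
    D, L = donors.shape
    match = donors == hap[None, :]
    emit = np.where(match, 1.0 - M, M).T          # (L, D)
    rho = np.exp(-n_rate * np.diff(gpos))         # stay probabilities (L-1,)

    alpha = np.empty((L, D))
    scale = np.empty(L)
    a = emit[0] / D
    scale[0] = a.sum()
    alpha[0] = a / scale[0]
    for l in range(1, L):
        r = rho[l - 1]
        a = emit[l] * (r * alpha[l - 1] + (1.0 - r) / D)
        scale[l] = a.sum()
        alpha[l] = a / scale[l]

    beta = np.empty((L, D))
    beta[L - 1] = 1.0
    for l in range(L - 2, -1, -1):
        r = rho[l]
        eb = emit[l + 1] * beta[l + 1]
        beta[l] = (r * eb + (1.0 - r) * eb.sum() / D) / scale[l + 1]

    post = alpha * beta
    post /= post.sum(axis=1, keepdims=True)

    # expected entries into each state: initial occupancy + sum over steps of
    # P(switch into d at step l) = (1-r)/D * (1 - alpha_{l-1}(d)) * e_l(d) * beta_l(d) / c_l
    entries = post[0].copy()
    for l in range(1, L):
        r = rho[l - 1]
        entries += ((1.0 - r) / D) * (1.0 - alpha[l - 1]) * emit[l] * beta[l] / scale[l]
    return post, entries


def paint_linked(recipient: np.ndarray, panel: DonorPanel, params: PaintingParams):
    """Paint one haplotype under the linked copying HMM.

    Returns ``(genome_fraction, chunk_counts)``, both ``(D,)`` arrays over
    the panel's donor haplotypes.  Genome fractions sum to 1; chunk counts
    are expected numbers of donor chunks summed over chromosomes.
    """
    if params.mode != "linked":
        raise ValueError("paint_linked requires mode='linked'")
    recipient = np.asarray(recipient, dtype=np.int8)
    if recipient.shape[0] != panel.haplotypes.shape[1]:
        raise ValueError("recipient length does not match panel sites")
    D = panel.n_donors
    frac = np.zeros(D)
    chunks = np.zeros(D)
    total_w = 0.0
    for c in np.unique(panel.chrom):
        sel = panel.chrom == c
        gpos = panel.genetic_pos[sel]
        post, entries = _forward_backward(
            recipient[sel], panel.haplotypes[:, sel], gpos,
            params.mutation_rate, params.switch_rate,
        )
        w = _site_weights(gpos)
        frac += post.T @ w
        chunks += entries
        total_w += w.sum()
    return frac / total_w, chunks


def paint_unlinked(recipient: np.ndarray, panel: DonorPanel, params: PaintingParams):
    """Expected per-donor matching counts under the unlinked model.

    At each site independently the posterior over donors is proportional
    to the emission (1-M on match, M on mismatch); the returned ``(D,)``
    vector sums matching posteriors over sites ("matching chunk counts").
    """
    if params.mode != "unlinked":
        raise ValueError("paint_unlinked requires mode='unlinked'")
    recipient = np.asarray(recipient, dtype=np.int8)
    if recipient.shape[0] != panel.haplotypes.shape[1]:
        raise ValueError("recipient length does not match panel sites")
    M = params.mutation_rate
    match = panel.haplotypes == recipient[None, :]
    emit = np.where(match, 1.0 - M, M)            # (D, L)
    return (emit / emit.sum(axis=0, keepdims=True)).sum(axis=1)


# ---------------------------------------------------------------------------
# all-vs-all painting
# ---------------------------------------------------------------------------

def _aggregate_by_group(values: np.ndarray, group_labels: Sequence[str],
                        groups: Sequence[str]) -> np.ndarray:
    out = np.zeros(len(groups))
    gl = np.asarray(group_labels)
    for j, g in enumerate(groups):
        out[j] = values[gl == g].sum()
    return out


def paint_all(
    haplotypes: np.ndarray,
    genetic_pos: np.ndarray,
    labels: Sequence[str],
    params: PaintingParams | None = None,
    *,
    chrom: np.ndarray | None = None,
    individual_ids: Sequence[str] | None = None,
    exclude_same_label: bool = False,
) -> PaletteMatrix:
    """Paint every individual against all others; aggregate by group label.

    ``haplotypes`` is ``(2N, L)`` phased; individual ``i`` owns rows
    ``2i, 2i+1`` and is painted with a panel of all haplotypes except its
    own (``self_exclusion="individual"``), or except the painted haplotype
    only.  ``exclude_same_label=True`` additionally removes all donors
    sharing the recipient's label (the stringent drift-removal panel).
    Each haplotype's donor-level result is aggregated by donor group, the
    recipient's two haplotypes are averaged, and rows are normalized.
    Linked mode yields genome-fraction palettes; unlinked mode yields
    row-normalized matching chunk counts.
    """
    if params is None:
        params = PaintingParams()
    haplotypes = np.asarray(haplotypes, dtype=np.int8)
    n2, L = haplotypes.shape
    if n2 % 2 or n2 < 4:
        raise ValueError("need phased haplotypes for at least 2 individuals")
    N = n2 // 2
    labels = list(labels)
    if len(labels) != N:
        raise ValueError(f"{N} individuals but {len(labels)} labels")
    if individual_ids is None:
        individual_ids = [f"ind{i}" for i in range(N)]
    individual_ids = list(individual_ids)

    groups = list(dict.fromkeys(labels))          # order of first appearance
    hap_owner = np.repeat(np.arange(N), 2)
    hap_label = np.repeat(np.asarray(labels, dtype=object), 2)

    rows = np.zeros((N, len(groups)))
    for i in range(N):
        for h in (2 * i, 2 * i + 1):
            if params.self_exclusion == "individual":
                keep = hap_owner != i
            else:
                keep = np.arange(n2) != h
            if exclude_same_label:
                keep &= hap_label != labels[i]
            if not keep.any():
                raise ValueError(f"empty donor panel for individual {individual_ids[i]}")
            panel = DonorPanel(
                haplotypes=haplotypes[keep],
                owner_ids=[individual_ids[o] for o in hap_owner[keep]],
                group_labels=list(hap_label[keep]),
                genetic_pos=genetic_pos,
                chrom=chrom,
            )
            if params.mode == "linked":
                frac, _ = paint_linked(haplotypes[h], panel, params)
            else:
                frac = paint_unlinked(haplotypes[h], panel, params)
            rows[i] += _aggregate_by_group(frac, panel.group_labels, groups)
    rows /= rows.sum(axis=1, keepdims=True)
    payload = "genome_fraction" if params.mode == "linked" else "chunk_count"
    pm = PaletteMatrix(rows, individual_ids, groups, payload=payload)
    return pm


def paint_dataset(dataset, params: PaintingParams | None = None,
                  **kwargs) -> PaletteMatrix:
    """Convenience wrapper running :func:`paint_all` on a SimulatedDataset."""
    return paint_all(
        dataset.haplotypes, dataset.genetic_pos, dataset.labels, params,
        chrom=dataset.chrom, individual_ids=dataset.individual_ids, **kwargs,
    )
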
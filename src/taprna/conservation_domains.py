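"""Sliding-window cross-species conservation along transcripts.

Each window of the human spliced transcript is locally aligned against the
entire mouse transcript (patches need not be collinear between species);
windows at or above the identity threshold merge into conserved patches.
Binned patch profiles feed agglomerative clustering into minor and major
conservation classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .alignment import ScoringScheme, local_align
from .models import TranscriptModel


@dataclass
class ConservedDomainProfile:
    """Per-window cross-species identity with merged conserved patches."""

    transcript_id: str
    transcript_length: int
    window: int
    step: int
    window_starts: list[int] = field(default_factory=list)
    window_identity: list[float] = field(default_factory=list)
    conserved_patches: list[tuple[int, int]] = field(default_factory=list)

    @property
    def conserved_fraction(self) -> float:
        covered = sum(e - s for s, e in self.conserved_patches)
        return covered / self.transcript_length if self.transcript_length else 0.0


def _merge_windows(starts: Sequence[int], identities: Sequence[float],
                   window: int, min_identity: float,
                   length: int) -> list[tuple[int, int]]:
    patches: list[list[int]] = []
    for s, ident in zip(starts, identities):
        if ident < min_identity:
            continue
        lo, hi = s, min(s + window, length)
        if patches and lo <= patches[-1][1]:
            patches[-1][1] = max(patches[-1][1], hi)
        else:
            patches.append([lo, hi])
    return [tuple(p) for p in patches]


def sliding_window_profile(human_tx_seq: str, mouse_tx_seq: str,
                           window: int = 100, step: int = 50,
                           min_identity: float = 0.6,
                           scoring: ScoringScheme | None = None,
                           transcript_id: str = "") -> ConservedDomainProfile:
    """Window-by-window identity of the human transcript against the full
    mouse transcript; windows with identity >= ``min_identity`` merge into
    patches on human transcript coordinates."""
    if window > len(human_tx_seq):
        raise ValueError("window exceeds transcript length")
    if step < 1:
        raise ValueError("step must be >= 1")
    scoring = scoring or ScoringScheme()
    length = len(human_tx_seq)
    starts = list(range(0, length - window + 1, step))
    if starts and starts[-1] + window < length:
        starts.append(length - window)  # tail window so no bases are blind
    identities = []
    for s in starts:
        aln = local_align(human_tx_seq[s:s + window], mouse_tx_seq, scoring)
        # identity over the window, not just the aligned core: short
        # high-identity slivers must not qualify a whole window
        matches = aln.identity * aln.n_aligned_columns
        identities.append(matches / window if window else 0.0)
    return ConservedDomainProfile(
        transcript_id=transcript_id, transcript_length=length,
        window=window, step=step, window_starts=starts,
        window_identity=identities,
        conserved_patches=_merge_windows(starts, identities, window,
                                         min_identity, length),
    )


def conservation_group(profile: ConservedDomainProfile,
                       high: float = 0.73, medium: float = 0.30) -> str:
    """Four-way conservation class from the conserved fraction.

    ``none`` iff no base is covered by a qualifying patch; otherwise the
    highest threshold met (closed lower bounds), with ``low`` for any
    positive fraction below ``medium``.
    """
    if not high > medium > 0:
        raise ValueError("thresholds must be strictly decreasing")
    frac = profile.conserved_fraction
    if frac == 0:
        return "none"
    if frac >= high:
        return "high"
    if frac >= medium:
        return "medium"
    return "low"


def binned_profile_matrix(profiles: Sequence[ConservedDomainProfile],
                          n_bins: int = 50) -> np.ndarray:
    """Transcripts x bins matrix of the fraction of each length-normalised
    bin covered by conserved patches."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    mat = np.zeros((len(profiles), n_bins))
    for i, prof in enumerate(profiles):
        length = prof.transcript_length
        edges = np.linspace(0, length, n_bins + 1)
        for s, e in prof.conserved_patches:
            lo_bin = np.searchsorted(edges, s, side="right") - 1
            hi_bin = np.searchsorted(edges, e, side="left")
            for b in range(lo_bin, min(hi_bin, n_bins)):
                ov = min(e, edges[b + 1]) - max(s, edges[b])
                width = edges[b + 1] - edges[b]
                if width > 0 and ov > 0:
                    mat[i, b] += ov / width
    return np.clip(mat, 0.0, 1.0)


def cluster_profiles(matrix: np.ndarray, n_minor: int = 16,
                     n_major: int = 4) -> tuple[np.ndarray, np.ndarray,
                                                np.ndarray]:
    """Agglomerative (Euclidean, average-linkage) clustering of binned
    profiles, cut at ``n_minor`` and ``n_major`` clusters.

    Labels are renumbered by first occurrence so the assignment is
    deterministic given input order; centroids are per-minor-cluster bin
    means.
    """
    matrix = np.asarray(matrix, dtype=float)
    n_rows = matrix.shape[0]
    if not 1 <= n_major <= n_minor <= n_rows:
        raise ValueError("need n_major <= n_minor <= number of rows")
    if n_rows == 1:
        return np.array([0]), np.array([0]), matrix.copy()
    Z = linkage(matrix, method="average", metric="euclidean")
    minor = _renumber(fcluster(Z, t=n_minor, criterion="maxclust"))
    major = _renumber(fcluster(Z, t=n_major, criterion="maxclust"))
    centroids = np.vstack([
        matrix[minor == lab].mean(axis=0) for lab in range(minor.max() + 1)
    ])
    return minor, major, centroids


def _renumber(labels: np.ndarray) -> np.ndarray:
    seen: dict[int, int] = {}
    out = np.empty(len(labels), dtype=int)
    for i, lab in enumerate(labels):
        out[i] = seen.setdefault(lab, len(seen))
    return out


def transcript_conservation_score(transcript: TranscriptModel,
                                  track: Mapping[str, np.ndarray]) -> float:
    """Mean per-base conservation score over exonic positions only."""
    scores = track[transcript.chrom]
    vals = np.concatenate([
        np.asarray(scores[e.start:e.end], dtype=float)
        for e in transcript.exons
    ])
    return float(vals.mean())
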
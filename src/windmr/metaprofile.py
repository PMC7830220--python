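"""Length-normalized methylation metaprofiles over genes and TEs.

Each feature body is divided into ``n_bins`` near-equal bins, flanked by
``flank_len`` bp upstream and downstream split into the same number of
bins, giving 3·n_bins bins per feature (20+20+20 by default).  Bin 1 is
always the distal 5' flank in the feature's own orientation: for minus
strand features the bin sequence is reversed.  Bin levels are pooled
read-weighted across features (Σm/Σt over every site falling in that bin
of any feature).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomicInterval
from .methylome import MethylomeTrack


class FeatureTooShortWarning(UserWarning):
    pass


@dataclass
class MetaProfile:
    """Pooled bin levels for one context over one feature class."""

    context: str
    feature_class: str
    levels: np.ndarray  # 3*n_bins values, NaN where no data
    m_sum: np.ndarray
    t_sum: np.ndarray
    n_features: int
    n_bins: int
    flank_len: int

    def to_frame(self) -> pd.DataFrame:
        n = self.n_bins
        zone = ["up"] * n + ["body"] * n + ["down"] * n
        return pd.DataFrame(
            {
                "bin_index": np.arange(1, 3 * n + 1),
                "zone": zone,
                "context": self.context,
                "level": self.levels,
                "n_reads": self.t_sum.astype(int),
            }
        )


def _split(
    start: int, end: int, n_bins: int, remainder_at_start: bool = True
) -> list[tuple[int, int]]:
    """Split [start,end) into n_bins near-equal pieces.

    Remainder base pairs go to the leading (5'-most) bins; for minus-strand
    features the caller passes ``remainder_at_start=False`` so that, after
    the bin order is reversed, the 5'-leading bins still carry the remainder
    and profiles are exactly strand-symmetric.
    """
    length = end - start
    base, rem = divmod(length, n_bins)
    if remainder_at_start:
        sizes = [base + 1] * rem + [base] * (n_bins - rem)
    else:
        sizes = [base] * (n_bins - rem) + [base + 1] * rem
    bounds = np.concatenate([[0], np.cumsum(sizes)]) + start
    return [(int(bounds[i]), int(bounds[i + 1])) for i in range(n_bins)]


def bin_feature(
    feature: GenomicInterval,
    flank_len: int = 2000,
    n_bins: int = 20,
    chrom_len: int | None = None,
) -> list[tuple[int, int]]:
    """The 3·n_bins (start, end) bin intervals of a feature, 5'→3'.

    Remainder base pairs are spread over the leading bins of each zone.
    Flank bins clipped at a chromosome edge may be empty (start == end);
    they simply contribute no sites.  Raises ``ValueError`` when the body
    is shorter than ``n_bins``.
    """
    if len(feature) < n_bins:
        raise ValueError(
            f"feature {feature.chrom}:{feature.start}-{feature.end} shorter than {n_bins} bins"
        )
    up_start = max(0, feature.start - flank_len)
    down_end = feature.end + flank_len
    if chrom_len is not None:
        down_end = min(down_end, chrom_len)
    fwd = feature.strand != "-"
    upstream = _bins_maybe_empty(up_start, feature.start, n_bins, fwd)
    body = _split(feature.start, feature.end, n_bins, fwd)
    downstream = _bins_maybe_empty(feature.end, down_end, n_bins, fwd)
    bins = upstream + body + downstream
    if not fwd:
        bins = bins[::-1]
    return bins


def _bins_maybe_empty(
    start: int, end: int, n_bins: int, remainder_at_start: bool
) -> list[tuple[int, int]]:
    if end <= start:
        return [(start, start)] * n_bins
    return _split(start, end, n_bins, remainder_at_start)


def feature_metaprofile(
    track: MethylomeTrack,
    features: list[GenomicInterval],
    context: str,
    flank_len: int = 2000,
    n_bins: int = 20,
    feature_class: str = "feature",
    chrom_len: dict[str, int] | None = None,
) -> MetaProfile:
    """Pooled metaprofile of one context over a feature class.

    Features shorter than ``n_bins`` bp are skipped with a warning.
    Overlapping features each receive their sites independently — the
    profile is descriptive, so double counting across features is accepted.
    Raises ``ValueError`` when no feature is usable.
    """
    df = track.df
    df = df[df["context"] == context]
    by_chrom = {
        chrom: (grp["pos"].to_numpy(), grp["m"].to_numpy(), grp["t"].to_numpy())
        for chrom, grp in df.groupby("chrom", observed=True)
    }
    m_sum = np.zeros(3 * n_bins)
    t_sum = np.zeros(3 * n_bins)
    n_used = 0
    for feature in features:
        try:
            bins = bin_feature(
                feature, flank_len, n_bins,
                None if chrom_len is None else chrom_len.get(feature.chrom),
            )
        except ValueError:
            warnings.warn(
                f"skipping feature {feature.chrom}:{feature.start}-{feature.end}: "
                f"shorter than {n_bins} bins",
                FeatureTooShortWarning,
                stacklevel=2,
            )
            continue
        data = by_chrom.get(feature.chrom)
        if data is None:
            n_used += 1
            continue
        pos, m, t = data
        cm = np.concatenate([[0], np.cumsum(m)])
        ct = np.concatenate([[0], np.cumsum(t)])
        starts = np.array([b[0] for b in bins])
        ends = np.array([b[1] for b in bins])
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="left")
        m_sum += cm[hi] - cm[lo]
        t_sum += ct[hi] - ct[lo]
        n_used += 1
    if n_used == 0:
        raise ValueError("no usable features (all shorter than the bin count?)")
    with np.errstate(invalid="ignore", divide="ignore"):
        levels = np.where(t_sum > 0, m_sum / np.where(t_sum > 0, t_sum, 1), np.nan)
    return MetaProfile(
        context=context, feature_class=feature_class, levels=levels,
        m_sum=m_sum, t_sum=t_sum, n_features=n_used, n_bins=n_bins,
        flank_len=flank_len,
    )


def plot_metaprofile(profiles: list[MetaProfile], path=None, ax=None):
    """Quick matplotlib rendering of one or more metaprofiles (optional hook)."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for prof in profiles:
        x = np.arange(1, 3 * prof.n_bins + 1)
        ax.plot(x, prof.levels, label=f"{prof.feature_class} {prof.context}")
    n = profiles[0].n_bins
    for edge in (n + 0.5, 2 * n + 0.5):
        ax.axvline(edge, color="grey", lw=0.5, ls="--")
    ax.set_xlabel("bin (5' flank | body | 3' flank)")
    ax.set_ylabel("methylation level")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
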
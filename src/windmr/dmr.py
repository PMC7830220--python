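"""Sliding-window differential methylation caller.

The procedure, per cytosine context:

1. Tile each chromosome with sliding windows (200 bp, step 50 bp).
2. In each window, pool the read counts of cytosines covered at depth ≥ 4
   in *both* samples into a 2×2 table and apply Fisher's exact test;
   adjust p-values genome-wide per context with Benjamini–Hochberg.
3. Keep windows with adjusted p < 0.01 and an over 2.5-fold change of the
   read-weighted methylation level; union overlapping same-direction
   windows into candidate regions.
4. Within candidate regions, test every common cytosine individually;
   sites with exact-test p < 0.01 are differentially methylated cytosines
   (DMCs).
5. Candidate regions containing at least 7 DMCs become DMRs, keeping the
   region extent; adjacent same-direction DMRs separated by ≤ 100 bp are
   merged, with levels and DMC counts recomputed on the merged span.

Direction is reported for sample B relative to sample A: *hyper* means B's
level exceeds A's.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import CONTEXTS, GenomeSequence, GenomicInterval
from .methylome import MethylomeTrack
from .stats import bh_adjust, fisher_exact_vec

__all__ = [
    "DmrParams",
    "Dmr",
    "generate_windows",
    "paired_sites",
    "test_windows",
    "select_candidate_windows",
    "union_candidates",
    "call_dmcs",
    "merge_spans",
    "assemble_dmrs",
    "call_context_dmrs",
    "call_all_dmrs",
    "classify_direction",
    "dmr_summary",
    "dmrs_to_bed",
    "read_dmr_bed",
]


@dataclass(frozen=True)
class DmrParams:
    """All caller thresholds, with the standard WGBS sliding-window defaults."""

    window_size: int = 200
    step: int = 50
    min_coverage: int = 4
    q_max: float = 0.01
    min_fold: float = 2.5
    dmc_p: float = 0.01
    dmc_min: int = 7
    merge_gap: int = 100


@dataclass
class Dmr:
    """One differentially methylated region (sample B vs sample A)."""

    chrom: str
    start: int
    end: int
    context: str
    direction: str  # hyper | hypo
    n_dmc: int
    level_a: float
    level_b: float
    fold_change: float  # max(level)/min(level); inf when the low level is 0
    qmin: float  # smallest window q-value among source windows

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)

    def __len__(self) -> int:
        return self.end - self.start


def generate_windows(chrom_len: int, size: int = 200, step: int = 50) -> np.ndarray:
    """Start positions of sliding windows: 0, step, 2·step, … ≤ chrom_len − size.

    No partial trailing window is emitted; a chromosome shorter than one
    window yields an empty array.
    """
    if step <= 0 or size <= 0 or step > size:
        raise ValueError("need 0 < step <= size")
    if size > chrom_len:
        return np.zeros(0, dtype=np.int64)
    return np.arange(0, chrom_len - size + 1, step, dtype=np.int64)


def paired_sites(
    track_a: MethylomeTrack,
    track_b: MethylomeTrack,
    context: str | None = None,
    min_coverage: int = 4,
) -> pd.DataFrame:
    """Sites covered at ≥ min_coverage in BOTH samples, with both count pairs.

    Columns: chrom, pos, strand, context, m_a, t_a, m_b, t_b, sorted by
    coordinate.  Per-cytosine two-sample tests are only defined on this
    intersection.
    """
    a = track_a.df
    b = track_b.df
    if context is not None:
        a = a[a["context"] == context]
        b = b[b["context"] == context]
    a = a[a["t"] >= min_coverage]
    b = b[b["t"] >= min_coverage]
    merged = a.merge(
        b, on=["chrom", "pos", "strand"], suffixes=("_a", "_b"), how="inner"
    )
    merged = merged.rename(columns={"context_a": "context"}).drop(columns=["context_b"])
    return merged.sort_values(["chrom", "pos", "strand"], kind="stable").reset_index(drop=True)


def test_windows(
    track_a: MethylomeTrack,
    track_b: MethylomeTrack,
    context: str,
    windows: dict[str, np.ndarray],
    window_size: int = 200,
    min_coverage: int = 4,
) -> pd.DataFrame:
    """Fisher-test every window's pooled 2×2 read-count table.

    ``windows`` maps chromosome → window start positions.  Windows with no
    commonly covered context site are skipped.  The returned frame has one
    row per tested window with columns chrom, start, end, n_sites, m_a, u_a,
    m_b, u_b, level_a, level_b, p, q; q is BH-adjusted across *all* tested
    windows of this context.
    """
    pairs = paired_sites(track_a, track_b, context, min_coverage)
    frames = []
    for chrom, starts in windows.items():
        if len(starts) == 0:
            continue
        sub = pairs[pairs["chrom"] == chrom]
        pos = sub["pos"].to_numpy()
        if pos.size == 0:
            continue
        cum_ma = np.concatenate([[0], np.cumsum(sub["m_a"].to_numpy())])
        cum_ta = np.concatenate([[0], np.cumsum(sub["t_a"].to_numpy())])
        cum_mb = np.concatenate([[0], np.cumsum(sub["m_b"].to_numpy())])
        cum_tb = np.concatenate([[0], np.cumsum(sub["t_b"].to_numpy())])
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, starts + window_size, side="left")
        n_sites = hi - lo
        keep = n_sites > 0
        if not keep.any():
            continue
        lo, hi, s = lo[keep], hi[keep], starts[keep]
        m_a = cum_ma[hi] - cum_ma[lo]
        t_a = cum_ta[hi] - cum_ta[lo]
        m_b = cum_mb[hi] - cum_mb[lo]
        t_b = cum_tb[hi] - cum_tb[lo]
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": s,
                    "end": s + window_size,
                    "n_sites": n_sites[keep],
                    "m_a": m_a,
                    "u_a": t_a - m_a,
                    "m_b": m_b,
                    "u_b": t_b - m_b,
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "n_sites", "m_a", "u_a", "m_b", "u_b",
                     "level_a", "level_b", "p", "q"]
        )
    tests = pd.concat(frames, ignore_index=True)
    tests["level_a"] = tests["m_a"] / (tests["m_a"] + tests["u_a"])
    tests["level_b"] = tests["m_b"] / (tests["m_b"] + tests["u_b"])
    tests["p"] = fisher_exact_vec(
        tests["m_a"].to_numpy(), tests["u_a"].to_numpy(),
        tests["m_b"].to_numpy(), tests["u_b"].to_numpy(),
    )
    tests["q"] = bh_adjust(tests["p"].to_numpy())
    return tests


def _fold_change(level_a: np.ndarray, level_b: np.ndarray) -> np.ndarray:
    """max/min level ratio; inf when exactly one level is 0, 1 when both are."""
    hi = np.maximum(level_a, level_b)
    lo = np.minimum(level_a, level_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(lo > 0, hi / np.where(lo > 0, lo, 1.0), np.where(hi > 0, np.inf, 1.0))
    return fold


def select_candidate_windows(
    tests: pd.DataFrame, q_max: float = 0.01, min_fold: float = 2.5
) -> pd.DataFrame:
    """Windows with q < q_max and an over-min_fold change of the level.

    Fold change is the ratio of the higher to the lower read-weighted level,
    strict inequality; a zero low level with a positive high level counts as
    an infinite fold and passes.
    """
    if len(tests) == 0:
        return tests.copy()
    fold = _fold_change(tests["level_a"].to_numpy(), tests["level_b"].to_numpy())
    keep = (tests["q"].to_numpy() < q_max) & (fold > min_fold)
    out = tests[keep].copy()
    out["direction"] = np.where(out["level_b"] > out["level_a"], "hyper", "hypo")
    return out.reset_index(drop=True)


def union_candidates(candidates: pd.DataFrame) -> pd.DataFrame:
    """Union overlapping or bookended same-direction windows into regions.

    Opposite-direction windows never merge.  Returns chrom, start, end,
    direction, qmin sorted by coordinate.
    """
    if len(candidates) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "direction", "qmin"])
    rows = []
    for (chrom, direction), grp in candidates.groupby(["chrom", "direction"], observed=True):
        grp = grp.sort_values("start")
        cur_s, cur_e, cur_q = None, None, np.inf
        for w in grp.itertuples(index=False):
            if cur_s is None:
                cur_s, cur_e, cur_q = w.start, w.end, w.q
            elif w.start <= cur_e:  # overlap or bookend
                cur_e = max(cur_e, w.end)
                cur_q = min(cur_q, w.q)
            else:
                rows.append((chrom, cur_s, cur_e, direction, cur_q))
                cur_s, cur_e, cur_q = w.start, w.end, w.q
        rows.append((chrom, cur_s, cur_e, direction, cur_q))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "direction", "qmin"])
    return out.sort_values(["chrom", "start"]).reset_index(drop=True)


def call_dmcs(
    track_a: MethylomeTrack,
    track_b: MethylomeTrack,
    regions: pd.DataFrame,
    context: str,
    p_max: float = 0.01,
    min_coverage: int = 4,
    _pairs: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-cytosine exact tests inside candidate regions.

    Every context site covered ≥ min_coverage in both samples is tested with
    a two-sided Fisher exact test on its ((m, u), (m, u)) table; sites with
    p < p_max are DMCs.  Returns chrom, pos, strand, m_a, t_a, m_b, t_b, p,
    region_id.
    """
    pairs = _pairs if _pairs is not None else paired_sites(track_a, track_b, context, min_coverage)
    picks = []
    for rid, reg in enumerate(regions.itertuples(index=False)):
        sub = pairs[pairs["chrom"] == reg.chrom]
        pos = sub["pos"].to_numpy()
        lo = np.searchsorted(pos, reg.start, side="left")
        hi = np.searchsorted(pos, reg.end, side="left")
        if hi > lo:
            piece = sub.iloc[lo:hi].copy()
            piece["region_id"] = rid
            picks.append(piece)
    if not picks:
        return pd.DataFrame(
            columns=["chrom", "pos", "strand", "context", "m_a", "t_a", "m_b", "t_b", "p", "region_id"]
        )
    sites = pd.concat(picks, ignore_index=True)
    sites["p"] = fisher_exact_vec(
        sites["m_a"].to_numpy(), (sites["t_a"] - sites["m_a"]).to_numpy(),
        sites["m_b"].to_numpy(), (sites["t_b"] - sites["m_b"]).to_numpy(),
    )
    return sites[sites["p"] < p_max].reset_index(drop=True)


def classify_direction(level_a: float, level_b: float) -> str:
    """hyper iff the case sample's (B) level exceeds the control's (A)."""
    if level_b > level_a:
        return "hyper"
    if level_b < level_a:
        return "hypo"
    raise ValueError("equal levels: direction undefined (excluded by the fold filter)")


def _region_levels(pairs_chrom: pd.DataFrame, start: int, end: int) -> tuple[float, float, int]:
    pos = pairs_chrom["pos"].to_numpy()
    lo = np.searchsorted(pos, start, side="left")
    hi = np.searchsorted(pos, end, side="left")
    piece = pairs_chrom.iloc[lo:hi]
    t_a, t_b = piece["t_a"].sum(), piece["t_b"].sum()
    la = float(piece["m_a"].sum() / t_a) if t_a else float("nan")
    lb = float(piece["m_b"].sum() / t_b) if t_b else float("nan")
    return la, lb, hi - lo


def merge_spans(
    spans: list[tuple[str, int, int, str, float]], merge_gap: int = 100
) -> list[tuple[str, int, int, str, float]]:
    """Merge (chrom, start, end, direction, qmin) spans with gap ≤ merge_gap.

    Only same-chromosome, same-direction spans merge; the merged span takes
    the smallest qmin.  Idempotent and invariant to input order; after
    merging, every remaining same-direction gap exceeds ``merge_gap``.
    """
    merged: list[tuple[str, int, int, str, float]] = []
    for chrom, direction in sorted({(s[0], s[3]) for s in spans}):
        group = sorted(s for s in spans if s[0] == chrom and s[3] == direction)
        cur = list(group[0])
        for nxt in group[1:]:
            if nxt[1] - cur[2] <= merge_gap:
                cur[2] = max(cur[2], nxt[2])
                cur[4] = min(cur[4], nxt[4])
            else:
                merged.append(tuple(cur))
                cur = list(nxt)
        merged.append(tuple(cur))
    merged.sort(key=lambda s: (s[0], s[1]))
    return merged


def assemble_dmrs(
    regions: pd.DataFrame,
    dmcs: pd.DataFrame,
    pairs: pd.DataFrame,
    context: str,
    dmc_min: int = 7,
    merge_gap: int = 100,
) -> list[Dmr]:
    """DMC-count filter and gap merging.

    Candidate regions containing at least ``dmc_min`` DMCs become DMRs,
    keeping the candidate-region extent (the union of their significant
    windows).  Same-direction DMRs separated by ≤ ``merge_gap`` bp are then
    merged; levels and DMC counts are recomputed on each merged span.
    Output is coordinate-sorted.
    """
    prelim: list[tuple[str, int, int, str, float]] = []
    for rid, reg in enumerate(regions.itertuples(index=False)):
        sub = dmcs[dmcs["region_id"] == rid] if len(dmcs) else dmcs
        if len(sub) < dmc_min:
            continue
        prelim.append((reg.chrom, int(reg.start), int(reg.end), reg.direction, reg.qmin))

    merged = merge_spans(prelim, merge_gap)

    dmrs: list[Dmr] = []
    for chrom, start, end, direction, qmin in merged:
        pairs_chrom = pairs[pairs["chrom"] == chrom]
        la, lb, _ = _region_levels(pairs_chrom, start, end)
        if len(dmcs):
            n_dmc = int(
                ((dmcs["chrom"] == chrom) & (dmcs["pos"] >= start) & (dmcs["pos"] < end)).sum()
            )
        else:
            n_dmc = 0
        fold = float(_fold_change(np.array([la]), np.array([lb]))[0])
        dmrs.append(
            Dmr(
                chrom=chrom, start=start, end=end, context=context,
                direction=direction, n_dmc=n_dmc, level_a=la, level_b=lb,
                fold_change=fold, qmin=float(qmin),
            )
        )
    dmrs.sort(key=lambda d: (d.chrom, d.start))
    return dmrs


def call_context_dmrs(
    track_a: MethylomeTrack,
    track_b: MethylomeTrack,
    genome: GenomeSequence,
    context: str,
    params: DmrParams = DmrParams(),
) -> tuple[list[Dmr], pd.DataFrame]:
    """Run the full caller for one context; returns (DMRs, window tests)."""
    windows = {
        chrom: generate_windows(genome.chrom_len[chrom], params.window_size, params.step)
        for chrom in genome.chrom_names
    }
    tests = test_windows(
        track_a, track_b, context, windows, params.window_size, params.min_coverage
    )
    candidates = select_candidate_windows(tests, params.q_max, params.min_fold)
    regions = union_candidates(candidates)
    pairs = paired_sites(track_a, track_b, context, params.min_coverage)
    dmcs = call_dmcs(
        track_a, track_b, regions, context, params.dmc_p, params.min_coverage, _pairs=pairs
    )
    dmrs = assemble_dmrs(regions, dmcs, pairs, context, params.dmc_min, params.merge_gap)
    return dmrs, tests


def call_all_dmrs(
    track_a: MethylomeTrack,
    track_b: MethylomeTrack,
    genome: GenomeSequence,
    params: DmrParams = DmrParams(),
) -> dict[str, list[Dmr]]:
    """Caller over all three contexts (BH applied per context genome-wide)."""
    return {
        ctx: call_context_dmrs(track_a, track_b, genome, ctx, params)[0]
        for ctx in CONTEXTS
    }


def dmr_summary(dmrs: list[Dmr]) -> pd.DataFrame:
    """Per-context totals: counts by direction, total length, |Δlevel| classes.

    ``n_delta_gt50`` counts DMRs whose between-sample level difference
    exceeds 0.5; ``hyper + hypo == total`` by construction.
    """
    rows = []
    for ctx in CONTEXTS:
        sub = [d for d in dmrs if d.context == ctx]
        n_hyper = sum(d.direction == "hyper" for d in sub)
        n_hypo = sum(d.direction == "hypo" for d in sub)
        deltas = [abs(d.level_b - d.level_a) for d in sub]
        rows.append(
            {
                "context": ctx,
                "total": len(sub),
                "hyper": n_hyper,
                "hypo": n_hypo,
                "total_length_bp": sum(len(d) for d in sub),
                "n_delta_gt50": sum(x > 0.5 for x in deltas),
                "n_delta_le50": sum(x <= 0.5 for x in deltas),
            }
        )
    return pd.DataFrame(rows)


def dmrs_to_bed(dmrs: list[Dmr], path) -> None:
    """BED6+4: name=context|direction, score=−log10 qmin, then levels, n_dmc, fold."""
    with open(path, "w") as fh:
        for d in dmrs:
            score = min(1000.0, -np.log10(max(d.qmin, 1e-300)))
            fh.write(
                f"{d.chrom}\t{d.start}\t{d.end}\t{d.context}|{d.direction}\t"
                f"{score:.2f}\t.\t{d.level_a:.4f}\t{d.level_b:.4f}\t{d.n_dmc}\t"
                f"{'inf' if np.isinf(d.fold_change) else f'{d.fold_change:.3f}'}\n"
            )


def read_dmr_bed(path) -> list[Dmr]:
    dmrs = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            ctx, direction = f[3].split("|")
            dmrs.append(
                Dmr(
                    chrom=f[0], start=int(f[1]), end=int(f[2]), context=ctx,
                    direction=direction, n_dmc=int(f[8]), level_a=float(f[6]),
                    level_b=float(f[7]),
                    fold_change=float("inf") if f[9] == "inf" else float(f[9]),
                    qmin=10 ** (-float(f[4])),
                )
            )
    return dmrs
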
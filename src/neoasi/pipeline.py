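"""Windowed ASI estimation, per-subject averaging and the MSD stability grid.

An ASI estimate from a single long window and the mean of several short-window
estimates are competing ways to spend the same 10 minutes of quiet-sleep EEG.
This module implements the window *schemes* (one 10-min window, four 2.5-min
windows, two 5-min windows, ...), per-subject epoch means, and the test-retest
stability criterion used to choose among schemes and derivation pairs:

    MSD = (1/n) * sum_i (ASI_1,i - ASI_2,i)^2

where ASI_1,i and ASI_2,i are subject i's (average) ASI over the first and
second 10-min quiet-sleep epoch.  The lowest MSD identifies the most stable
(pair, scheme) combination.  A Mann-Whitney U comparison of subsequent versus
separated quiet-sleep epochs checks that stability does not depend on where
the two epochs came from.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .asi import ASIConfig, asi_for_window
from .errors import (
    DataQualityError,
    EpochLengthError,
    IncompleteSubjectError,
    StatisticsError,
)
from .records import DerivationPair, EEGRecord, STANDARD_PAIRS

__all__ = [
    "WindowScheme",
    "SCHEMES",
    "SubjectASISummary",
    "split_epoch",
    "windowed_asi_mean",
    "summarize_subject",
    "msd",
    "optimization_grid",
    "epoch_sources_compare",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowScheme:
    """How to spend (part of) a 10-min epoch: n contiguous equal windows."""

    scheme_id: str
    window_minutes: float
    n_windows: int

    def __post_init__(self) -> None:
        if self.window_minutes * self.n_windows > 10 + 1e-9:
            raise ValueError("scheme must fit within a 10-min epoch")
        if self.n_windows < 1 or self.window_minutes <= 0:
            raise ValueError("need at least one window of positive length")

    @property
    def window_seconds(self) -> float:
        return self.window_minutes * 60.0

    @property
    def total_seconds(self) -> float:
        return self.window_seconds * self.n_windows


#: The five candidate schemes, keyed by id.  "4x2.5" averages four 2.5-min
#: windows; "1x10" is the single full-epoch estimate; "2x2.5" and "1x5" use
#: only the first 5 min of the epoch.
SCHEMES: dict[str, WindowScheme] = {
    "1x10": WindowScheme("1x10", 10.0, 1),
    "4x2.5": WindowScheme("4x2.5", 2.5, 4),
    "2x5": WindowScheme("2x5", 5.0, 2),
    "2x2.5": WindowScheme("2x2.5", 2.5, 2),
    "1x5": WindowScheme("1x5", 5.0, 1),
}


@dataclass
class SubjectASISummary:
    """Windowed ASI means for one subject, pair and scheme, both epochs."""

    subject_id: str
    pair: DerivationPair
    scheme: WindowScheme
    asi_epoch1: float | None
    asi_epoch2: float | None
    per_window_values: dict[int, list[float]] = field(default_factory=dict)
    group: str | None = None
    pma_weeks: float | None = None

    @property
    def complete(self) -> bool:
        return self.asi_epoch1 is not None and self.asi_epoch2 is not None

    @property
    def squared_difference(self) -> float:
        if not self.complete:
            raise IncompleteSubjectError(
                f"subject {self.subject_id} is missing an epoch mean")
        return (self.asi_epoch1 - self.asi_epoch2) ** 2


def split_epoch(epoch: tuple[float, float],
                scheme: WindowScheme) -> list[tuple[float, float]]:
    """Split a ``[start, end)`` epoch into the scheme's contiguous windows.

    Windows start at the epoch start; an epoch shorter than the scheme's
    total length raises :class:`EpochLengthError`.
    """
    start, end = epoch
    need = scheme.total_seconds
    if end - start < need - 1e-9:
        raise EpochLengthError(
            f"epoch of {end - start:.0f} s too short for scheme "
            f"{scheme.scheme_id} ({need:.0f} s)")
    w = scheme.window_seconds
    return [(start + i * w, start + (i + 1) * w) for i in range(scheme.n_windows)]


def _window_clean(record: EEGRecord, window: tuple[float, float]) -> bool:
    """Quality policy: reject any window touching annotated artifact or NaN."""
    for ann in record.annotations_tagged("artifact"):
        if ann.overlaps(*window):
            return False
    i0 = int(round(window[0] * record.fs))
    i1 = int(round(window[1] * record.fs))
    return not np.isnan(record.data[:, i0:i1]).any()


def windowed_asi_mean(record: EEGRecord, pair: DerivationPair,
                      epoch: tuple[float, float], scheme: WindowScheme,
                      config: ASIConfig = ASIConfig(),
                      mode: str = "strict") -> tuple[float, list[float]]:
    """Mean ASI over the scheme's windows of one epoch, plus per-window values.

    In ``strict`` mode (the faithful default for manually selected clean
    epochs) any rejected window raises :class:`DataQualityError`; in
    ``tolerant`` mode the mean is taken over surviving windows with a logged
    count.
    """
    if mode not in ("strict", "tolerant"):
        raise ValueError(f"unknown rejection mode {mode!r}")
    windows = split_epoch(epoch, scheme)
    values: list[float] = []
    n_rejected = 0
    for w in windows:
        if not _window_clean(record, w):
            if mode == "strict":
                raise DataQualityError(
                    f"window [{w[0]:.0f}, {w[1]:.0f}) rejected (artifact/NaN) "
                    "in strict mode")
            n_rejected += 1
            continue
        values.append(asi_for_window(record, pair, w, config).asi)
    if n_rejected:
        logger.warning("%d/%d windows rejected in epoch [%.0f, %.0f)",
                       n_rejected, len(windows), *epoch)
    if not values:
        raise DataQualityError("all windows rejected in epoch")
    return float(np.mean(values)), values


def summarize_subject(record: EEGRecord, pair: DerivationPair,
                      scheme: WindowScheme,
                      config: ASIConfig = ASIConfig(),
                      qs_tags: tuple[str, str] = ("QS1", "QS2"),
                      mode: str = "strict") -> SubjectASISummary:
    """Epoch-level ASI means for one subject from its two annotated QS epochs."""
    summary = SubjectASISummary(
        subject_id=str(record.meta.get("subject_id", "?")),
        pair=pair, scheme=scheme, asi_epoch1=None, asi_epoch2=None,
        group=record.meta.get("group"), pma_weeks=record.meta.get("pma_weeks"),
    )
    for k, tag in enumerate(qs_tags, start=1):
        anns = record.annotations_tagged(tag)
        if not anns:
            raise IncompleteSubjectError(
                f"subject {summary.subject_id}: no annotation tagged {tag!r}")
        epoch = (anns[0].start, anns[0].end)
        mean, values = windowed_asi_mean(record, pair, epoch, scheme, config, mode)
        setattr(summary, f"asi_epoch{k}", mean)
        summary.per_window_values[k] = values
    return summary


def msd(summaries: list[SubjectASISummary]) -> float:
    """Mean squared difference between each subject's two epoch-level ASIs.

    Raises :class:`IncompleteSubjectError` listing the ids of any subject
    missing an epoch mean.
    """
    if not summaries:
        raise StatisticsError("msd needs at least one subject")
    missing = [s.subject_id for s in summaries if not s.complete]
    if missing:
        raise IncompleteSubjectError(
            f"subjects missing an epoch mean: {', '.join(missing)}")
    return float(np.mean([s.squared_difference for s in summaries]))


def optimization_grid(
    cohort: list[EEGRecord],
    pairs: tuple[DerivationPair, ...] = STANDARD_PAIRS,
    schemes: tuple[WindowScheme, ...] = tuple(SCHEMES.values()),
    config: ASIConfig = ASIConfig(),
    qs_tags: tuple[str, str] = ("QS1", "QS2"),
    mode: str = "strict",
) -> pd.DataFrame:
    """MSD for every (scheme, pair) cell, with row/column mean margins.

    Returns a DataFrame with scheme ids as rows and pair names as columns,
    plus a ``mean_per_scheme`` column and ``mean_per_pair`` row; the argmin
    cell is recorded in ``df.attrs["argmin"]``.  Cells whose subjects fail
    (strict-mode rejection, missing epochs) are left NaN with a warning, and
    margins are computed over available cells only.
    """
    grid = pd.DataFrame(index=[s.scheme_id for s in schemes],
                        columns=[p.name for p in pairs], dtype=float)
    for scheme in schemes:
        for pair in pairs:
            try:
                summaries = [summarize_subject(rec, pair, scheme, config,
                                               qs_tags, mode)
                             for rec in cohort]
                grid.loc[scheme.scheme_id, pair.name] = msd(summaries)
            except Exception as exc:  # partial grid is still useful
                logger.warning("grid cell (%s, %s) failed: %s",
                               scheme.scheme_id, pair.name, exc)
    grid["mean_per_scheme"] = grid.mean(axis=1, skipna=True)
    pair_means = grid.drop(columns="mean_per_scheme").mean(axis=0, skipna=True)
    grid.loc["mean_per_pair"] = pd.concat([pair_means, pd.Series(
        {"mean_per_scheme": np.nan})])
    core = grid.drop(index="mean_per_pair").drop(columns="mean_per_scheme")
    if core.notna().any().any():
        flat = core.stack()
        grid.attrs["argmin"] = tuple(flat.idxmin())  # (scheme_id, pair_name)
    return grid


def epoch_sources_compare(
    subsequent: list[SubjectASISummary],
    separated: list[SubjectASISummary],
) -> tuple[float, float, float]:
    """Compare ASI stability for subsequent vs. separated quiet-sleep epochs.

    Returns ``(MSD_subsequent, MSD_separated, p)`` where p is the two-sided
    Mann-Whitney U p-value comparing the per-subject squared epoch
    differences between the two conditions (exact null distribution when
    both arms have n <= 20, normal approximation with tie correction
    otherwise).
    """
    if len(subsequent) < 2 or len(separated) < 2:
        raise StatisticsError("need at least 2 subjects per condition")
    d_sub = [s.squared_difference for s in subsequent]
    d_sep = [s.squared_difference for s in separated]
    method = "exact" if max(len(d_sub), len(d_sep)) <= 20 else "asymptotic"
    res = spstats.mannwhitneyu(d_sub, d_sep, alternative="two-sided",
                               method=method)
    return float(np.mean(d_sub)), float(np.mean(d_sep)), float(res.pvalue)
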
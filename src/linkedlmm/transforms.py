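"""Variable transformations, fixation selection, and covariate centering.

Raw fixation reports carry skewed covariates (durations in ms, word
frequencies per million, launch distances in characters).  Before they enter
a linear mixed model each is transformed to an approximately linear scale:

========================  =========================  =====================
variable                  raw unit                   transformation
========================  =========================  =====================
fixation location x       character index (1-based)  x/(l+1) - 1/2
fixation duration t       milliseconds               ln t
word length l             letters                    1/l
word frequency f          occurrences per million    log10(f+1)
predictability p          probability                (1/2) logit(p)
launch-site distance d    characters (>= 1)          log2 d
========================  =========================  =====================

Relative location 0 is the middle character of the word and -1/2 the space
preceding it.  Predictabilities of exactly 0 or 1 are first pulled into the
open unit interval using the number of complete cloze protocols.  All
covariates (never the responses) are centered on their sample mean; the
centering constants are retained so new data can be placed on the same
scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RAW_COLUMNS",
    "RAW_SEQUENCE_COLUMNS",
    "COVARIATE_COLUMNS",
    "FixationTable",
    "relative_location",
    "adjust_predictability",
    "scaled_logit",
    "transform_table",
    "select_single_fixations",
]

#: processed-dialect input columns (one row per selected single fixation)
RAW_COLUMNS = [
    "subject", "sentence", "word", "word_index", "char_index", "duration_ms",
    "launch_chars", "skip",
    "len_n", "len_nm1", "len_np1",
    "freq_n", "freq_nm1", "freq_np1",
    "pred_n", "pred_nm1", "pred_np1",
]

#: raw-sequence dialect columns (one row per fixation, temporal order)
RAW_SEQUENCE_COLUMNS = [
    "subject", "sentence", "fixation_order", "word_index", "char_index",
    "duration_ms",
]

#: transformed covariate columns that get centered (responses excluded)
COVARIATE_COLUMNS = [
    "log2_launch",
    "inv_len_nm1", "logit_pred_nm1", "log_freq_nm1",
    "inv_len_n", "logit_pred_n", "log_freq_n",
    "inv_len_np1", "logit_pred_np1", "log_freq_np1",
]


class InvalidPositionError(ValueError):
    """Character index outside the word (including its leading space)."""


@dataclass
class FixationTable:
    """Analysis-ready fixation table.

    Attributes
    ----------
    data:
        One row per selected fixation.  Contains the raw columns, the
        transformed columns (``rel_loc``, ``log_dur``, ``log2_launch``,
        ``inv_len_*``, ``log_freq_*``, ``logit_pred_*``) and, for every
        covariate, a centered twin with suffix ``_c``.
    centering:
        Mapping covariate name -> mean subtracted to produce the ``_c``
        column.  Apply to new data via :func:`transform_table`'s
        ``centering`` argument.
    n_dropped:
        Rows removed because a required field was missing.
    """

    data: pd.DataFrame
    centering: dict[str, float] = field(default_factory=dict)
    n_dropped: int = 0

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.data)


def relative_location(char_index, word_length, strict: bool = True):
    """Code a 1-based character index relative to the word center.

    ``char_index`` 0 denotes the space preceding the word and maps to -1/2;
    the middle character of an odd-length word maps to 0.  Vectorized.

    With ``strict`` (the default, appropriate for recorded data) a
    character index outside the word raises; ``strict=False`` extends the
    same linear map beyond the word, which synthetic corpora generated
    from an unbounded Gaussian location model require.
    """
    ci = np.asarray(char_index, dtype=float)
    wl = np.asarray(word_length, dtype=float)
    if np.any(wl < 1):
        raise InvalidPositionError("word_length must be >= 1")
    if strict and np.any((ci < 0) | (ci > wl)):
        bad = np.argwhere((ci < 0) | (ci > wl)).ravel()
        raise InvalidPositionError(
            f"char_index outside [0, word_length] at positions {bad[:5].tolist()}"
        )
    out = ci / (wl + 1.0) - 0.5
    return out if out.ndim else float(out)


def adjust_predictability(p, n_complete: int):
    """Pull probabilities of exactly 0 or 1 into the open unit interval.

    A predictability of 0 becomes ``1/(2 n_complete)`` and 1 becomes
    ``(2 n_complete - 1)/(2 n_complete)``, where ``n_complete`` is the
    number of complete cloze protocols behind the norms; every other value
    passes through unchanged.
    """
    if n_complete < 1:
        raise ValueError("n_complete must be >= 1")
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("predictability outside [0, 1]")
    lo = 1.0 / (2 * n_complete)
    out = np.where(arr == 0.0, lo, np.where(arr == 1.0, 1.0 - lo, arr))
    return out if out.ndim else float(out)


def scaled_logit(p):
    """Half-logit ``(1/2) ln(p/(1-p))``, comparable in scale to probits."""
    arr = np.asarray(p, dtype=float)
    if np.any((arr <= 0) | (arr >= 1)):
        raise ValueError("scaled_logit requires p in the open interval (0, 1); "
                         "adjust boundary values first")
    out = 0.5 * np.log(arr / (1.0 - arr))
    return out if out.ndim else float(out)


def transform_table(
    raw: pd.DataFrame,
    n_complete: int = 83,
    centering: dict[str, float] | None = None,
    strict_location: bool = True,
) -> FixationTable:
    """Apply all variable transformations and center the covariates.

    Parameters
    ----------
    raw:
        Processed-dialect table with :data:`RAW_COLUMNS`.
    n_complete:
        Number of complete predictability protocols; boundary
        predictabilities are adjusted with it before the logit.
    centering:
        Previously stored centering constants.  When given, they are used
        verbatim (for scoring new data on a fitted scale); otherwise means
        are estimated from ``raw`` after dropping incomplete rows.
    strict_location:
        Enforce ``0 <= char_index <= len_n`` (recorded data).  Synthetic
        corpora drawn from the unbounded Gaussian location model pass
        ``False``.
    """
    missing = [c for c in RAW_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")

    df = raw.copy()
    n_before = len(df)
    df = df.dropna(subset=RAW_COLUMNS).reset_index(drop=True)
    n_dropped = n_before - len(df)

    for col, label in [("duration_ms", "duration_ms"), ("launch_chars", "launch_chars")]:
        bad = df.index[df[col] <= 0]
        if len(bad):
            raise ValueError(f"non-positive {label} at row(s) {bad[:5].tolist()}")

    df["rel_loc"] = relative_location(df["char_index"].to_numpy(),
                                      df["len_n"].to_numpy(),
                                      strict=strict_location)
    df["log_dur"] = np.log(df["duration_ms"].to_numpy(dtype=float))
    df["log2_launch"] = np.log2(df["launch_chars"].to_numpy(dtype=float))
    for suf in ("n", "nm1", "np1"):
        df[f"inv_len_{suf}"] = 1.0 / df[f"len_{suf}"].to_numpy(dtype=float)
        df[f"log_freq_{suf}"] = np.log10(df[f"freq_{suf}"].to_numpy(dtype=float) + 1.0)
        adj = adjust_predictability(df[f"pred_{suf}"].to_numpy(dtype=float), n_complete)
        df[f"logit_pred_{suf}"] = scaled_logit(adj)

    skip = df["skip"].to_numpy()
    if not np.isin(skip, (0, 1)).all():
        raise ValueError("skip indicator must be 0 or 1")
    df["skip"] = skip.astype(int)

    if centering is None:
        centering = {c: float(df[c].mean()) for c in COVARIATE_COLUMNS}
    for c in COVARIATE_COLUMNS:
        df[f"{c}_c"] = df[c] - centering[c]

    return FixationTable(data=df, centering=dict(centering), n_dropped=n_dropped)


def select_single_fixations(word_indices) -> pd.DataFrame:
    """Flag single first-pass fixations bounded by forward saccades.

    ``word_indices`` is the temporally ordered sequence of fixated word
    positions within one trial.  Consecutive fixations on the same word form
    a run.  A run is *first-pass* when, before it starts, neither its word
    nor any word to the right has been fixated; a first-pass run of length
    one is a *single* fixation.  A single fixation additionally qualifies
    only when both the incoming and the outgoing saccade move rightward in
    word index, which excludes trial-initial and trial-final fixations.  The
    incoming saccade of a qualified fixation is labelled *skipping* when it
    launched from a word left of word n-1.

    Returns a DataFrame with one row per fixation and boolean columns
    ``first_pass``, ``single``, ``forward_bounded``, ``qualifies`` plus the
    integer ``skip`` label (only meaningful where ``qualifies``).
    """
    words = list(word_indices)
    n = len(words)
    first_pass = [False] * n
    single = [False] * n
    fwd = [False] * n
    skip = [0] * n

    # run decomposition over consecutive identical word indices
    i = 0
    max_seen = -np.inf
    while i < n:
        j = i
        while j + 1 < n and words[j + 1] == words[i]:
            j += 1
        is_fp = words[i] > max_seen
        for k in range(i, j + 1):
            first_pass[k] = is_fp
        if is_fp and j == i:
            single[i] = True
        max_seen = max(max_seen, words[i])
        i = j + 1

    for k in range(n):
        fwd[k] = (
            0 < k < n - 1
            and words[k - 1] < words[k]
            and words[k] < words[k + 1]
        )
        if fwd[k]:
            skip[k] = int(words[k - 1] < words[k] - 1)

    out = pd.DataFrame(
        {
            "word_index": words,
            "first_pass": first_pass,
            "single": single,
            "forward_bounded": fwd,
        }
    )
    out["qualifies"] = out["first_pass"] & out["single"] & out["forward_bounded"]
    out["skip"] = skip
    return out
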
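"""Per-professional messaging-behavior measures from the event log.

Four behavior families: how fast messages are read, how fast
conversations are answered, daily message throughput, and typical
message lengths sent and received.  All times are minutes; a
professional with no qualifying events for a measure gets NaN rather
than zero.
"""

from __future__ import annotations

from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .events import MessageEvent, events_frame

MINUTE = np.timedelta64(60, "s")


def read_times(events: Sequence[MessageEvent]) -> pd.Series:
    """Mean minutes from sent to read, per receiving professional.

    Only read messages contribute; a professional whose incoming
    messages were never read is absent from the result.
    """
    df = events_frame(events)
    if df.empty:
        return pd.Series(dtype=float, name="mean_read_time")
    read = df.dropna(subset=["read_at"]).copy()
    read["minutes"] = (read["read_at"] - read["sent_at"]) / pd.Timedelta(minutes=1)
    out = read.groupby("receiver_id")["minutes"].mean()
    out.index.name = "node_id"
    return out.rename("mean_read_time")


def response_times(
    events: Sequence[MessageEvent],
    attribution: Literal["responder", "dyad"] = "responder",
) -> pd.Series:
    """Mean minutes from a conversation's first message to the first
    message by the other party, per professional.

    One interval per conversation that got a response; attributed to
    the responder by default (it measures their responsiveness), or to
    both members of the dyad with ``attribution='dyad'``.
    """
    df = events_frame(events)
    if df.empty:
        return pd.Series(dtype=float, name="mean_response_time")
    df = df.sort_values(["sent_at", "sender_id"], kind="mergesort")
    intervals: dict[str, list[float]] = {}
    for _, conv in df.groupby("conversation_id", sort=True):
        first = conv.iloc[0]
        initiator = first["sender_id"]
        replies = conv[conv["sender_id"] != initiator]
        if replies.empty:
            continue
        reply = replies.iloc[0]
        minutes = (reply["sent_at"] - first["sent_at"]) / pd.Timedelta(minutes=1)
        targets = [reply["sender_id"]] if attribution == "responder" else [initiator, reply["sender_id"]]
        for pid in targets:
            intervals.setdefault(pid, []).append(float(minutes))
    result = pd.Series(
        {pid: float(np.mean(vals)) for pid, vals in sorted(intervals.items())},
        dtype=float,
        name="mean_response_time",
    )
    result.index.name = "node_id"
    return result


def daily_volume(
    events: Sequence[MessageEvent],
    denominator: Literal["active_days", "calendar_days"] = "active_days",
    window_days: Optional[int] = None,
) -> pd.Series:
    """(Sent + received messages) per day, per professional.

    ``active_days`` divides by the number of distinct dates on which
    the professional sent or received at least one message (robust to
    enrollment gaps); ``calendar_days`` divides by the study-window
    length, which must then be supplied.
    """
    df = events_frame(events)
    if df.empty:
        return pd.Series(dtype=float, name="daily_volume")
    stacked = pd.concat(
        [
            df[["sender_id", "sent_at"]].rename(columns={"sender_id": "node_id"}),
            df[["receiver_id", "sent_at"]].rename(columns={"receiver_id": "node_id"}),
        ],
        ignore_index=True,
    )
    counts = stacked.groupby("node_id").size()
    if denominator == "calendar_days":
        if not window_days or window_days <= 0:
            raise ValueError("calendar_days mode requires a positive window_days")
        days = pd.Series(window_days, index=counts.index, dtype=float)
    else:
        stacked["date"] = stacked["sent_at"].dt.normalize()
        days = stacked.groupby("node_id")["date"].nunique().astype(float)
    out = counts / days
    out.index.name = "node_id"
    return out.rename("daily_volume")


def char_length_profiles(events: Sequence[MessageEvent]) -> pd.DataFrame:
    """Mean characters per message sent and received, per professional.

    A professional with no traffic in one direction gets NaN for that
    direction.
    """
    df = events_frame(events)
    if df.empty:
        return pd.DataFrame(columns=["mean_sent_chars", "mean_received_chars"])
    sent = df.groupby("sender_id")["char_length"].mean().rename("mean_sent_chars")
    received = df.groupby("receiver_id")["char_length"].mean().rename("mean_received_chars")
    out = pd.concat([sent, received], axis=1).sort_index()
    out.index.name = "node_id"
    return out


def behavior_table(
    events: Sequence[MessageEvent],
    denominator: Literal["active_days", "calendar_days"] = "active_days",
    window_days: Optional[int] = None,
    attribution: Literal["responder", "dyad"] = "responder",
) -> pd.DataFrame:
    """All behavior measures joined on professional id (NaN = no data)."""
    parts = [
        read_times(events),
        response_times(events, attribution),
        daily_volume(events, denominator, window_days),
        char_length_profiles(events),
    ]
    out = pd.concat(parts, axis=1).sort_index()
    out.index.name = "node_id"
    return out
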
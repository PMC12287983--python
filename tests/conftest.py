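"""Shared fixtures: toy event logs and graph builders."""

from __future__ import annotations

from datetime import datetime, timedelta

import networkx as nx
import pytest

from msgnet.events import MessageEvent

T0 = datetime(2023, 6, 1, 10, 0, 0)


def make_event(
    sender="A",
    receiver="B",
    conv="c1",
    sent=T0,
    read=None,
    chars=10,
    sender_role="nurse",
    receiver_role="nurse",
    sender_loc="inpatient",
    receiver_loc="inpatient",
):
    return MessageEvent(
        conversation_id=conv,
        sender_id=sender,
        receiver_id=receiver,
        sent_at=sent,
        read_at=read,
        char_length=chars,
        sender_role_raw=sender_role,
        receiver_role_raw=receiver_role,
        sender_location_raw=sender_loc,
        receiver_location_raw=receiver_loc,
    )


@pytest.fixture
def toy_events():
    """A->B twice, B->A once, A->C once (weights 5+7, 4, 3)."""
    return [
        make_event("A", "B", "c1", T0, chars=5),
        make_event("B", "A", "c1", T0 + timedelta(minutes=5), chars=4),
        make_event("A", "B", "c2", T0 + timedelta(hours=1), chars=7),
        make_event("A", "C", "c3", T0 + timedelta(hours=2), chars=3),
    ]


def digraph_from(edges: dict) -> nx.DiGraph:
    """Build a DiGraph from {(u, v): weight} with integer node labels."""
    g = nx.DiGraph()
    nodes = {u for u, _ in edges} | {v for _, v in edges}
    g.add_nodes_from(sorted(nodes))
    for (u, v), w in edges.items():
        g.add_edge(u, v, weight=w, message_count=1)
    return g
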
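"""Synthetic dyadic secure-messaging log generator.

Emulates the statistical shape of a hospital-system messaging log:
heavy-tailed partner counts per professional, a configurable share of
same-location (inpatient/outpatient) dyads, threaded conversations with
read receipts and responses, and log-normal message lengths and delays.
Also plants latent node groups with distinct network profiles so that
downstream cluster-recovery can be validated against ground truth.

Everything is driven by a single integer seed; the same config yields a
byte-identical log.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from datetime import datetime, timedelta
from typing import Optional, Sequence

import numpy as np

from .events import (
    LOCATION_INPATIENT,
    LOCATION_OUTPATIENT,
    ROLE_CATEGORIES,
    MessageEvent,
    Professional,
)

#: Role mix loosely shaped like a large inpatient-heavy health system:
#: nurses the largest group, then assistants/technicians and physicians,
#: pharmacists a small minority.
DEFAULT_ROLE_PROPORTIONS = {
    "physician": 0.15,
    "nurse": 0.35,
    "pharmacist": 0.02,
    "APP": 0.055,
    "therapist": 0.05,
    "medical_assistant_or_technician": 0.20,
    "social_work_or_case_management": 0.05,
    "other": 0.125,
}

#: Identity role map for synthetic logs (raw role string == category).
DEFAULT_ROLE_MAP = {r: r for r in ROLE_CATEGORIES}


@dataclass
class SimConfig:
    """Parameters of the synthetic log.

    Partner counts follow a truncated discrete power law
    ``P(k) ∝ k^-activity_exponent`` for ``1 <= k <= activity_cap``;
    the defaults give a median around 15 partners with a long tail.
    Message character lengths and read/response delays are log-normal
    (medians ~60 characters, ~20 and ~25 minutes).  ``location_homophily``
    is the probability that a dyad joins two same-location
    professionals; 0.5 means location plays no role on a balanced
    roster, 1.0 makes the network perfectly location-assortative.
    """

    n_professionals: int = 500
    role_proportions: dict = field(default_factory=lambda: dict(DEFAULT_ROLE_PROPORTIONS))
    p_inpatient: float = 0.71
    window_start: datetime = datetime(2023, 6, 1)
    window_end: datetime = datetime(2023, 11, 30, 23, 59, 59)
    location_homophily: float = 0.8
    activity_exponent: float = 1.0
    activity_cap: int = 300
    char_log_mu: float = math.log(60.0)
    char_log_sigma: float = 0.6
    read_delay_log_mu: float = math.log(20.0)   # minutes
    read_delay_log_sigma: float = 1.0
    response_delay_log_mu: float = math.log(25.0)  # minutes
    response_delay_log_sigma: float = 1.0
    n_hubs: int = 5
    hub_degree_multiplier: float = 5.0
    p_read: float = 0.9
    p_respond: float = 0.7
    p_continue: float = 0.55
    max_messages_per_conversation: int = 12
    seed: int = 0

    def validate(self) -> None:
        if self.n_professionals < 2:
            raise ValueError("n_professionals must be >= 2")
        probs = [self.p_inpatient, self.location_homophily, self.p_read,
                 self.p_respond, self.p_continue]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        total = sum(self.role_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"role_proportions sum to {total}, expected 1")
        if set(self.role_proportions) - set(ROLE_CATEGORIES):
            raise ValueError("role_proportions contains unknown roles")
        if self.window_start >= self.window_end:
            raise ValueError("window_start must precede window_end")
        if self.hub_degree_multiplier <= 0:
            raise ValueError("hub_degree_multiplier must be positive")


def _id_format(n: int) -> str:
    return "P{:0" + str(max(4, len(str(n)))) + "d}"


def simulate_roster(config: SimConfig, rng: Optional[np.random.Generator] = None) -> dict[str, Professional]:
    """Draw ``n_professionals`` ids with roles and locations from the config."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    fmt = _id_format(config.n_professionals)
    roles = sorted(config.role_proportions)
    p = np.array([config.role_proportions[r] for r in roles])
    p = p / p.sum()
    drawn_roles = rng.choice(len(roles), size=config.n_professionals, p=p)
    inpatient = rng.random(config.n_professionals) < config.p_inpatient
    roster = {}
    for i in range(config.n_professionals):
        pid = fmt.format(i)
        roster[pid] = Professional(
            id=pid,
            role=roles[drawn_roles[i]],
            location=LOCATION_INPATIENT if inpatient[i] else LOCATION_OUTPATIENT,
        )
    return roster


def _truncated_power_law(rng: np.random.Generator, exponent: float, cap: int, size: int) -> np.ndarray:
    k = np.arange(1, cap + 1, dtype=float)
    p = k ** (-exponent)
    p /= p.sum()
    return rng.choice(cap, size=size, p=p) + 1


def _sample_dyads(
    rng: np.random.Generator,
    ids: list[str],
    locations: np.ndarray,
    targets: np.ndarray,
    homophily: float,
) -> list[tuple[int, int]]:
    """Configuration-model-style dyad sampling with a homophily step.

    Nodes are matched proportionally to their remaining partner budget;
    for each dyad the partner pool is restricted to same-location nodes
    with probability ``homophily`` and to opposite-location nodes
    otherwise (falling back to the full pool when the restricted pool
    is exhausted).  Duplicate dyads and self-pairs are rejected.
    """
    n = len(ids)
    remaining = targets.astype(float).copy()
    seen: set[tuple[int, int]] = set()
    dyads: list[tuple[int, int]] = []
    partners: list[set[int]] = [set() for _ in range(n)]
    order = rng.permutation(n)
    for u in order:
        attempts = 0
        while remaining[u] > 0 and attempts < 4 * targets[u] + 8:
            attempts += 1
            same = rng.random() < homophily
            mask = (remaining > 0) & (locations == locations[u] if same else locations != locations[u])
            mask[u] = False
            cand = np.flatnonzero(mask)
            cand = cand[~np.isin(cand, list(partners[u]))] if partners[u] else cand
            if cand.size == 0:
                if homophily in (0.0, 1.0):
                    # hard constraint: never cross the location rule
                    break
                mask = remaining > 0
                mask[u] = False
                cand = np.flatnonzero(mask)
                cand = cand[~np.isin(cand, list(partners[u]))] if partners[u] else cand
                if cand.size == 0:
                    break
            w = remaining[cand]
            v = int(rng.choice(cand, p=w / w.sum()))
            key = (min(u, v), max(u, v))
            if key in seen:
                continue
            seen.add(key)
            partners[u].add(v)
            partners[v].add(int(u))
            dyads.append(key)
            remaining[u] -= 1
            remaining[v] -= 1
    dyads.sort()
    return dyads


def _lognormal_minutes(rng: np.random.Generator, mu: float, sigma: float) -> timedelta:
    return timedelta(seconds=int(round(float(rng.lognormal(mu, sigma)) * 60.0)))


def _conversation(
    rng: np.random.Generator,
    config: SimConfig,
    cid: str,
    a: Professional,
    b: Professional,
    t0: datetime,
) -> list[MessageEvent]:
    """One threaded dyadic conversation starting at ``t0``.

    The initiator sends the first message; with probability ``p_respond``
    the partner replies after a log-normal response delay; further
    messages alternate with probability ``p_continue`` each.  Each
    message is read with probability ``p_read`` after a log-normal
    read delay.
    """
    def make(sender: Professional, receiver: Professional, when: datetime) -> MessageEvent:
        when = when.replace(microsecond=0)
        read_at = None
        if rng.random() < config.p_read:
            read_at = when + _lognormal_minutes(
                rng, config.read_delay_log_mu, config.read_delay_log_sigma
            )
        chars = max(1, int(round(float(rng.lognormal(config.char_log_mu, config.char_log_sigma)))))
        return MessageEvent(
            conversation_id=cid,
            sender_id=sender.id,
            receiver_id=receiver.id,
            sent_at=when,
            read_at=read_at,
            char_length=chars,
            sender_role_raw=sender.role,
            receiver_role_raw=receiver.role,
            sender_location_raw=sender.location,
            receiver_location_raw=receiver.location,
        )

    initiator, responder = (a, b) if rng.random() < 0.5 else (b, a)
    events = [make(initiator, responder, t0)]
    if rng.random() >= config.p_respond:
        return events
    t = t0 + _lognormal_minutes(rng, config.response_delay_log_mu, config.response_delay_log_sigma)
    if t > config.window_end:
        return events
    events.append(make(responder, initiator, t))
    sender, receiver = initiator, responder
    while (
        len(events) < config.max_messages_per_conversation
        and rng.random() < config.p_continue
    ):
        t = t + _lognormal_minutes(rng, config.response_delay_log_mu, config.response_delay_log_sigma)
        if t > config.window_end:
            break
        events.append(make(sender, receiver, t))
        sender, receiver = receiver, sender
    return events


def simulate_event_log(
    config: SimConfig,
    roster: dict[str, Professional],
    rng: Optional[np.random.Generator] = None,
) -> list[MessageEvent]:
    """Generate the message stream for a roster.

    Partner counts are drawn from the truncated power law (hubs get
    ``hub_degree_multiplier`` times more), dyads are formed with the
    homophily step, and each dyad holds one or more threaded
    conversations placed uniformly in the study window.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    ids = sorted(roster)
    locations = np.array([roster[i].location == LOCATION_INPATIENT for i in ids])
    n = len(ids)
    targets = _truncated_power_law(rng, config.activity_exponent, config.activity_cap, n)
    for h in range(min(config.n_hubs, n)):
        targets[h] = min(n - 1, int(round(targets[h] * config.hub_degree_multiplier)))
    targets = np.minimum(targets, n - 1)
    dyads = _sample_dyads(rng, ids, locations, targets, config.location_homophily)

    span = (config.window_end - config.window_start).total_seconds()
    events: list[MessageEvent] = []
    counter = 0
    for u, v in dyads:
        n_conv = 1 + rng.poisson(0.5)
        for _ in range(n_conv):
            t0 = config.window_start + timedelta(seconds=float(rng.uniform(0, span * 0.95)))
            counter += 1
            events.extend(
                _conversation(rng, config, f"C{counter:07d}", roster[ids[u]], roster[ids[v]], t0)
            )
    events.sort(key=lambda e: (e.sent_at, e.conversation_id, e.sender_id))
    return events


# ---------------------------------------------------------------------------
# Planted-structure logs for cluster-recovery experiments
# ---------------------------------------------------------------------------

@dataclass
class GroupProfile:
    """Latent group: fraction of nodes, target partner count, wiring style.

    ``style='random'`` wires partners by degree-proportional stub
    matching across all random-style nodes; ``style='clique'`` wires the
    group into closed cliques of ``clique_size`` (plus one bridge per
    clique into the random part, keeping the graph connected) so its
    members get a high clustering coefficient.
    """

    name: str
    fraction: float
    degree: int
    style: str = "random"
    clique_size: int = 6


#: Default hub / connector / peripheral / cliquey structure.  Degree
#: tiers are geometrically spaced and the cliquey tier is wired into
#: closed cliques (one outside link per member), so the four groups
#: occupy distinct regions of the node-metric space.
DEFAULT_PROFILES = (
    GroupProfile("hub", 0.02, 120),
    GroupProfile("connector", 0.20, 40),
    GroupProfile("peripheral", 0.60, 6),
    GroupProfile("cliquey", 0.18, 6, style="clique", clique_size=6),
)


@dataclass
class PlantedLog:
    roster: dict[str, Professional]
    events: list[MessageEvent]
    labels: dict[str, str]          # id -> group name (ground truth)
    profiles: tuple


def _stub_match(rng: np.random.Generator, nodes: np.ndarray, degrees: np.ndarray) -> set[tuple[int, int]]:
    """Pair stubs uniformly; reject self-pairs and duplicates."""
    stubs = np.repeat(nodes, degrees)
    dyads: set[tuple[int, int]] = set()
    for _ in range(8):
        stubs = rng.permutation(stubs)
        half = len(stubs) // 2
        left, right = stubs[:half], stubs[half : 2 * half]
        leftover = []
        for u, v in zip(left.tolist(), right.tolist()):
            key = (min(u, v), max(u, v))
            if u == v or key in dyads:
                leftover.extend([u, v])
            else:
                dyads.add(key)
        if not leftover:
            break
        stubs = np.array(leftover)
    return dyads


def plant_metric_clusters(
    n: int = 2000,
    profiles: Sequence[GroupProfile] = DEFAULT_PROFILES,
    seed: int = 0,
    base: Optional[SimConfig] = None,
) -> PlantedLog:
    """Roster + log with ``k`` latent groups of distinct network profiles.

    Groups differ in partner count (hubs vs peripherals) and local
    wiring (cliquey groups sit in closed cliques), so the node-metric
    table separates them; the true labels ride along for recovery
    scoring.  Requires at least two groups; a warning is the only
    consequence of nearly overlapping degree profiles.
    """
    if len(profiles) < 2:
        raise ValueError("plant_metric_clusters requires k >= 2 group profiles")
    # clique-style groups separate on wiring, not degree, so only
    # random-style tiers are checked for degree overlap
    degs = sorted(p.degree for p in profiles if p.style == "random")
    if any(b < 1.5 * a for a, b in zip(degs, degs[1:])):
        import warnings

        warnings.warn("group degree profiles overlap; recovery may be ambiguous", stacklevel=2)
    if base is None:
        base = SimConfig(n_professionals=n, seed=seed)
    else:
        base.n_professionals = n
        base.seed = seed
    rng = np.random.default_rng(seed)
    roster = simulate_roster(base, rng)
    ids = sorted(roster)

    # assign group sizes (remainder to the largest group)
    sizes = [int(round(p.fraction * n)) for p in profiles]
    sizes[int(np.argmax(sizes))] += n - sum(sizes)
    labels: dict[str, str] = {}
    idx = rng.permutation(n)
    bounds = np.cumsum([0] + sizes)
    group_nodes: dict[str, np.ndarray] = {}
    for p, lo, hi in zip(profiles, bounds[:-1], bounds[1:]):
        members = np.sort(idx[lo:hi])
        group_nodes[p.name] = members
        for i in members:
            labels[ids[i]] = p.name

    random_nodes, random_degrees = [], []
    dyads: set[tuple[int, int]] = set()
    for p in profiles:
        members = group_nodes[p.name]
        if p.style == "clique":
            pool = np.concatenate([group_nodes[q.name] for q in profiles if q.style == "random"])
            members = rng.permutation(members)
            for start in range(0, len(members), p.clique_size):
                clique = members[start : start + p.clique_size]
                for a in range(len(clique)):
                    for b in range(a + 1, len(clique)):
                        dyads.add((min(clique[a], clique[b]), max(clique[a], clique[b])))
                # one outside link per member: keeps the clique reachable
                # while pinning the clustering coefficient near
                # (c-2)/(c) of neighbor pairs for every member
                for member in clique:
                    out = int(rng.choice(pool))
                    dyads.add((min(int(member), out), max(int(member), out)))
        else:
            noisy = np.maximum(1, rng.normal(p.degree, max(1.0, 0.05 * p.degree), len(members)))
            random_nodes.append(members)
            random_degrees.append(np.round(noisy).astype(int))
    dyads |= _stub_match(rng, np.concatenate(random_nodes), np.concatenate(random_degrees))

    span = (base.window_end - base.window_start).total_seconds()
    events: list[MessageEvent] = []
    for counter, (u, v) in enumerate(sorted(dyads), start=1):
        t0 = base.window_start + timedelta(seconds=float(rng.uniform(0, span * 0.95)))
        events.extend(
            _conversation(rng, base, f"C{counter:07d}", roster[ids[int(u)]], roster[ids[int(v)]], t0)
        )
    events.sort(key=lambda e: (e.sent_at, e.conversation_id, e.sender_id))
    return PlantedLog(roster=roster, events=events, labels=labels, profiles=tuple(profiles))


def write_ground_truth(path, planted: PlantedLog, seed: int) -> None:
    """JSON sidecar with the latent labels and a config echo."""
    payload = {
        "seed": seed,
        "labels": planted.labels,
        "profiles": [asdict(p) for p in planted.profiles],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
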
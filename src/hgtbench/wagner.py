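"""Asymmetric Wagner parsimony on binary presence/absence profiles.

Per gene family, a Sankoff dynamic program over states {absent, present}
reconstructs the minimum-cost gain/loss scenario on the species tree, with a
loss costing 1 and a gain costing r (the gain/loss penalty ratio). The ratio
is the method's stringency knob: raising r makes gains more expensive, so
fewer — but better supported — gains are inferred; as r exceeds the number
of leaves the reconstruction approaches a Dollo scenario (a single gain per
family).

Conventions (declared, since tools differ): a family present at the root is
charged one gain on the root's stem, reported with the root label as
recipient, so gain totals are comparable across families; cost ties during
traceback prefer absence, the conservative choice (fewer inferred presences,
hence fewer spurious gains).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .model import GainEvent, InferenceSet, PresenceAbsenceMatrix, SpeciesTree

__all__ = ["ParsimonyConfig", "infer_family_gains", "sweep_ratios"]

INF = float("inf")


@dataclass
class ParsimonyConfig:
    """Gain/loss penalty ratio and the sweep over it.

    gain_loss_ratio: gain cost r (loss cost fixed at 1).
    ratio_sweep: stringency axis for :func:`sweep_ratios`.
    tie_break: only "prefer-absence" is implemented.
    """

    gain_loss_ratio: float = 1.0
    ratio_sweep: Sequence[float] = field(default_factory=lambda: list(range(1, 9)))
    tie_break: str = "prefer-absence"

    def __post_init__(self) -> None:
        if self.gain_loss_ratio <= 0:
            raise ValueError("gain/loss ratio must be > 0")
        sweep = list(self.ratio_sweep)
        if sweep != sorted(set(sweep)):
            raise ValueError("ratio_sweep must be strictly increasing")
        if self.tie_break != "prefer-absence":
            raise ValueError(f"unknown tie-breaking policy {self.tie_break!r}")


def infer_family_gains(
    tree: SpeciesTree,
    presence: Mapping[str, int],
    config: ParsimonyConfig | None = None,
) -> tuple[list[str], list[str]]:
    """Minimum-cost gain and loss branches for one family.

    ``presence`` maps every leaf label to 0/1 (truthiness is used). Returns
    (gain branches, loss branches); a root-present family contributes a gain
    with the root label as recipient.
    """
    config = config or ParsimonyConfig()
    r = float(config.gain_loss_ratio)
    leaves = tree.leaf_labels
    missing = [l for l in leaves if l not in presence]
    if missing:
        raise ValueError(f"presence vector missing leaves: {missing[:5]}")
    if not any(presence[l] for l in leaves):
        return [], []

    # bottom-up: cost[label][s] = min cost of subtree given node state s
    cost: dict[str, tuple[float, float]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            state = 1 if presence[node.label] else 0
            cost[node.label] = (0.0, INF) if state == 0 else (INF, 0.0)
        else:
            c0 = c1 = 0.0
            for child in node.children:
                ch0, ch1 = cost[child.label]
                c0 += min(ch0, ch1 + r)  # parent absent: child gain costs r
                c1 += min(ch0 + 1.0, ch1)  # parent present: child loss costs 1
            cost[node.label] = (c0, c1)

    # root choice includes the stem-gain charge; ties prefer absence
    root = tree.root
    c0, c1 = cost[root.label]
    root_state = 0 if c0 <= c1 + r else 1

    gains: list[str] = []
    losses: list[str] = []
    if root_state == 1:
        gains.append(root.label)
    # top-down traceback
    stack = [(root, root_state)]
    while stack:
        node, state = stack.pop()
        for child in node.children:
            ch0, ch1 = cost[child.label]
            if state == 0:
                child_state = 0 if ch0 <= ch1 + r else 1
                if child_state == 1:
                    gains.append(child.label)
            else:
                child_state = 0 if ch0 + 1.0 <= ch1 else 1
                if child_state == 0:
                    losses.append(child.label)
            if not child.is_leaf:
                stack.append((child, child_state))
    return gains, losses


def scenario_cost(n_gains: int, n_losses: int, r: float) -> float:
    return n_gains * r + n_losses


def sweep_ratios(
    tree: SpeciesTree,
    matrix: PresenceAbsenceMatrix,
    config: ParsimonyConfig | None = None,
) -> InferenceSet:
    """Run the parsimony reconstruction per family at every sweep ratio.

    Stringency value = gain/loss penalty ratio; donors are absent (the
    method is implicit); confidence fixed at 1.
    """
    config = config or ParsimonyConfig()
    leaves = set(tree.leaf_labels)
    taxa = set(matrix.taxa)
    if taxa != leaves:
        raise ValueError(
            f"matrix taxa do not match tree leaves "
            f"(missing {sorted(leaves - taxa)[:3]}, extra {sorted(taxa - leaves)[:3]})"
        )
    binary = matrix.binary
    levels: dict[float, list[GainEvent]] = {}
    for ratio in config.ratio_sweep:
        rconf = ParsimonyConfig(gain_loss_ratio=ratio, tie_break=config.tie_break)
        events = []
        for family in matrix.families:
            row = binary.loc[family]
            presence = {t: int(row[t]) for t in matrix.taxa}
            gains, _ = infer_family_gains(tree, presence, rconf)
            events.extend(GainEvent(family=family, recipient=b) for b in gains)
        levels[float(ratio)] = events
    return InferenceSet(method="wagner-mp", levels=levels, axis="parameter")
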
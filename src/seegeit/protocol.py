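"""Frequency-division-multiplexed current-injection protocol.

Each injection pair carries 60 µA on its own carrier so that all injections
(and all voltage measurements) run simultaneously.  Carriers come from the
arithmetic set 8500, 8550, ..., 10000 Hz (31 available, all below the
12.5 kHz antialiasing cut-off at the 50 kHz acquisition rate).  Pairs are
chosen to intersect the epileptogenic region (preferring SEEG–SEEG across
probes and SEEG–ECoG combinations) and are never formed between two
contacts of the same SEEG probe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import HeadModel

CURRENT_AMPLITUDE = 60e-6  # A
CARRIER_SET = tuple(range(8500, 10001, 50))  # Hz, 31 carriers

__all__ = ["InjectionProtocol", "make_injection_protocol", "CARRIER_SET", "CURRENT_AMPLITUDE"]


@dataclass(frozen=True)
class InjectionProtocol:
    """(source, sink, carrier) triples with a common current amplitude."""

    pairs: tuple[tuple[str, str, float], ...]
    current_amplitude: float = CURRENT_AMPLITUDE
    reference_contact: str = "E01"

    @property
    def n_injections(self) -> int:
        return len(self.pairs)

    @property
    def carrier_frequencies(self) -> np.ndarray:
        return np.array([p[2] for p in self.pairs])

    def injection_contacts(self, i: int) -> tuple[str, str]:
        return self.pairs[i][0], self.pairs[i][1]

    def validate(self, model: HeadModel) -> None:
        probes = {e.id: (e.probe_id, e.kind) for e in model.electrodes}
        freqs = [p[2] for p in self.pairs]
        if len(set(freqs)) != len(freqs):
            raise ValueError("carrier frequencies must be distinct")
        if not set(freqs) <= set(float(f) for f in CARRIER_SET):
            raise ValueError("carriers must come from the 8500:50:10000 Hz set")
        if self.current_amplitude != CURRENT_AMPLITUDE:
            raise ValueError("current amplitude is fixed at 60 uA")
        for s, k, _f in self.pairs:
            ps, kinds = probes[s]
            pk, kindk = probes[k]
            if kinds == "seeg" and kindk == "seeg" and ps == pk:
                raise ValueError(f"pair ({s}, {k}) lies on one SEEG probe ({ps})")
            if self.reference_contact in (s, k):
                raise ValueError("the reference contact must not inject current")


def make_injection_protocol(
    model: HeadModel,
    n_pairs: int = 28,
    seed: int = 0,
    reference_contact: str = "E01",
) -> InjectionProtocol:
    """Draw a focus-intersecting injection protocol; pure in (model, n_pairs, seed).

    Candidate pairs exclude the reference contact and same-probe SEEG pairs.
    Sampling weight decays with the pair midpoint's distance to the cannula
    tip and favours SEEG involvement, so current paths preferentially span
    the lesioned region.  Carriers are assigned in ascending frequency order.
    """
    if n_pairs > len(CARRIER_SET):
        raise ValueError(f"n_pairs={n_pairs} exceeds the {len(CARRIER_SET)} available carriers")
    if len(model.seeg_probe_ids()) < 2:
        raise ValueError("protocol generation requires at least two SEEG probes")
    contacts = [e for e in model.electrodes if e.id != reference_contact]
    target = model.cannula_tip
    if target is None:
        target = np.mean([e.position for e in contacts if e.kind == "seeg"], axis=0)

    cand: list[tuple[str, str]] = []
    weights: list[float] = []
    for i in range(len(contacts)):
        for j in range(i + 1, len(contacts)):
            ei, ej = contacts[i], contacts[j]
            if ei.kind == "seeg" and ej.kind == "seeg" and ei.probe_id == ej.probe_id:
                continue
            mid = 0.5 * (ei.position + ej.position)
            d = float(np.linalg.norm(mid - target))
            w = np.exp(-d / 20.0)
            n_seeg = (ei.kind == "seeg") + (ej.kind == "seeg")
            w *= (1.0, 2.0, 3.0)[n_seeg]
            cand.append((ei.id, ej.id))
            weights.append(w)
    if n_pairs > len(cand):
        raise ValueError("not enough admissible pairs")

    rng = np.random.default_rng(seed)
    w = np.asarray(weights)
    order = rng.choice(len(cand), size=len(cand), replace=False, p=w / w.sum())

    # Greedy pick honouring a per-contact reuse cap so current spreads over
    # many contacts instead of hammering the few nearest the focus.
    use_count: dict[str, int] = {}
    chosen: list[tuple[str, str]] = []
    for idx in order:
        s, k = cand[idx]
        if use_count.get(s, 0) >= 4 or use_count.get(k, 0) >= 4:
            continue
        chosen.append((s, k))
        use_count[s] = use_count.get(s, 0) + 1
        use_count[k] = use_count.get(k, 0) + 1
        if len(chosen) == n_pairs:
            break
    if len(chosen) < n_pairs:  # cap too tight for this draw; fill without cap
        for idx in order:
            if cand[idx] not in chosen:
                chosen.append(cand[idx])
                if len(chosen) == n_pairs:
                    break

    chosen.sort()  # deterministic carrier assignment: ascending frequency
    freqs = [float(f) for f in CARRIER_SET[:n_pairs]]
    pairs = tuple((s, k, f) for (s, k), f in zip(chosen, freqs))
    proto = InjectionProtocol(pairs=pairs, reference_contact=reference_contact)
    proto.validate(model)
    return proto
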
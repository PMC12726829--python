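"""High-level single-cell model: morphology + biophysics + simulation.

`Model` bundles a discretized morphology, a biophysical configuration,
and a set of channel objects, and exposes the step-current and synaptic
protocols the validation module orchestrates.
"""

from __future__ import annotations

import numpy as np

from .channels import load_channel
from .distributions import BiophysConfig, apply_biophys
from .fixtures import make_toy_channels
from .morphology import build_segments, read_swc, split_to_sections
from .simulator import (
    StepCurrent,
    Synapse,
    build_circuit,
    make_synapse,
    run,
)

__all__ = ["Model", "nonlinearity_demo_model"]


def nonlinearity_demo_model(channels: dict | None = None) -> tuple["Model", int, float]:
    """The NMDA-spike demonstration setup: a thin distal apical branch.

    A passive ball-and-stick (300 µm × 0.8 µm stick, Rm = 10 kΩ·cm²,
    rest −70 mV) receives one compound AMPA+NMDA synapse (unitary AMPA
    gmax 0.05 nS, NMDA:AMPA ratio 4) at 90% of the stick.  Returns
    (model, synapse compartment, unitary weight in µS).
    """
    from .fixtures import make_ball_and_stick, make_passive_config

    model = Model(
        make_ball_and_stick(stick_length=300.0, stick_diam=0.8),
        make_passive_config(g_leak=1e-4, e_leak=-70.0),
        channels=channels,
        d_lambda=0.1,
    )
    return model, model.comp_at(1, 0.9), 5e-5


class Model:
    """A simulatable neuron model.

    Parameters
    ----------
    swc_text:
        SWC morphology content.
    config:
        Biophysical configuration (domains, groups, distributions).
    channels:
        Mechanism name → channel object.  Defaults to parsing the
        built-in toy channel set for any mechanism the config inserts.
    nseg, d_lambda:
        Discretization: fixed odd nseg per section, or the d_lambda rule.
    """

    def __init__(
        self,
        swc_text: str,
        config: BiophysConfig,
        channels: dict | None = None,
        nseg: int | None = None,
        d_lambda: float | None = 0.1,
        temperature: float | None = None,
    ):
        self.ptree = read_swc(swc_text)
        self.sectree = split_to_sections(self.ptree)
        g = config.globals
        self.stree = build_segments(
            self.sectree,
            nseg=nseg,
            d_lambda=d_lambda if nseg is None else None,
            Ra=g.get("Ra", 150.0),
            cm=g.get("cm", 1.0),
        )
        self.config = config
        self.temperature = temperature
        if channels is None:
            mods = make_toy_channels()
            needed = {m for ms in config.domains.values() for m in ms}
            channels = {name: load_channel(mods[name]) for name in needed if name in mods}
        self.channels = channels
        self.table = apply_biophys(config, self.stree)
        self.v_init = g.get("v_init", -65.0)

    # -- geometry helpers ----------------------------------------------

    def comp_at(self, section: int, x: float) -> int:
        """Compartment (segment) index containing position x of a section."""
        segs = self.stree.section_segments[section]
        n = len(segs)
        i = min(int(np.clip(x, 0.0, 1.0 - 1e-12) * n), n - 1)
        return segs[i]

    @property
    def soma_comp(self) -> int:
        return 0

    def circuit(self):
        return build_circuit(
            self.stree,
            self.table,
            channels=self.channels,
            reversals=self.config.reversals,
            temperature=self.temperature,
        )

    # -- protocols ------------------------------------------------------

    def run_step(
        self,
        amplitude: float,
        delay: float = 20.0,
        duration: float = 100.0,
        tstop: float | None = None,
        dt: float = 0.025,
        stim_comp: int | None = None,
        record_comps: tuple[int, ...] | None = None,
        theta: float = 1.0,
        t_equil: float = 0.0,
    ):
        """Step-current injection; returns {'v@<comp>': Trace}."""
        stim_comp = self.soma_comp if stim_comp is None else stim_comp
        record_comps = (stim_comp,) if record_comps is None else tuple(record_comps)
        tstop = tstop if tstop is not None else delay + duration + 50.0
        sys = self.circuit()
        stim = StepCurrent(stim_comp, amplitude, delay, duration)
        return run(
            sys,
            stimuli=[stim],
            recordings=[("v", c) for c in record_comps],
            tstop=tstop,
            dt=dt,
            v_init=self.v_init,
            theta=theta,
            t_equil=t_equil,
        )

    def run_synapses(
        self,
        synapses: list[Synapse],
        tstop: float = 100.0,
        dt: float = 0.025,
        record_comps: tuple[int, ...] = (0,),
        theta: float = 1.0,
        t_equil: float = 0.0,
    ):
        sys = self.circuit()
        return run(
            sys,
            synapses=synapses,
            recordings=[("v", c) for c in record_comps],
            tstop=tstop,
            dt=dt,
            v_init=self.v_init,
            theta=theta,
            t_equil=t_equil,
        )

    def run_protocol(self, settings_json: str, elements_csv: str):
        """Run a stimulation/recording protocol from JSON + CSV text.

        The JSON carries global settings (``tstop``, ``dt``, ``v_init``,
        ``t_equil``); the CSV one row per element with columns ``kind``
        (iclamp | synapse_population | recording), ``section``, ``x``
        and kind-specific parameters (``amp``, ``delay``, ``duration``
        for current clamps; ``n``, ``syn_kind``, ``gmax``, ``rate``,
        ``noise``, ``onset``, ``seed`` for populations).
        """
        import io
        import json as _json

        import pandas as pd

        from .simulator import SpikeSource, spike_train

        settings = _json.loads(settings_json)
        frame = pd.read_csv(io.StringIO(elements_csv))
        stimuli, synapses, record_comps = [], [], []
        for _, row in frame.iterrows():
            comp = self.comp_at(int(row["section"]), float(row["x"]))
            kind = row["kind"]
            if kind == "iclamp":
                stimuli.append(
                    StepCurrent(comp, float(row["amp"]), float(row["delay"]),
                                float(row["duration"]))
                )
            elif kind == "recording":
                record_comps.append(comp)
            elif kind == "synapse_population":
                seed = int(row.get("seed", 0))
                rng = np.random.default_rng(seed)
                src = SpikeSource(
                    rate=float(row["rate"]),
                    noise=float(row.get("noise", 0.0)),
                    onset=float(row.get("onset", 0.0)),
                    duration=float(row.get("duration", settings.get("tstop", 100.0))),
                )
                segs = self.stree.section_segments[int(row["section"])]
                from .simulator import place_synapses

                locs = place_synapses(
                    int(row["n"]), [self.stree.segments[i] for i in segs], rng
                )
                for seg, _x in locs:
                    synapses.extend(
                        make_synapse(
                            str(row.get("syn_kind", "AMPA")),
                            seg.idx,
                            gmax=float(row.get("gmax", 5e-4)),
                            spike_times=spike_train(src, rng),
                        )
                    )
            else:
                raise ValueError(f"unknown protocol element kind {kind!r}")
        if not record_comps:
            record_comps = [self.soma_comp]
        sys = self.circuit()
        return run(
            sys,
            stimuli=stimuli,
            synapses=synapses,
            recordings=[("v", c) for c in record_comps],
            tstop=float(settings.get("tstop", 100.0)),
            dt=float(settings.get("dt", 0.025)),
            v_init=float(settings.get("v_init", self.v_init)),
            t_equil=float(settings.get("t_equil", 0.0)),
        )

    def epsp_peak(
        self,
        weight: float,
        comp: int,
        kind: str = "AMPA_NMDA",
        nmda_ratio: float = 1.0,
        spike_time: float = 10.0,
        tstop: float = 120.0,
        dt: float = 0.025,
        record_comp: int | None = None,
    ) -> float:
        """Peak depolarization (mV) from one synaptic activation."""
        record_comp = comp if record_comp is None else record_comp
        if weight <= 0:
            return 0.0
        syns = make_synapse(
            kind, comp, gmax=weight, spike_times=[spike_time], nmda_ratio=nmda_ratio
        )
        traces = self.run_synapses(
            syns, tstop=tstop, dt=dt, record_comps=(record_comp,)
        )
        v = traces[f"v@{record_comp}"].values
        return float(np.max(v) - v[0])
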
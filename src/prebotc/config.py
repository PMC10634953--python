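"""Flat key-value configuration for model parameters.

Every channel parameter has a one-to-one config key (``neuron.na_m.x_half``,
``env.K_bath``, ``network.p_syn``, ...) so complete parameter sets round-trip
through human-readable text.  ``defaults.cfg`` shipped with the package holds
the standard parameter set (core channel values plus the calibrated
spike-shape kinetics).
"""

from __future__ import annotations

from dataclasses import fields, replace
from importlib import resources
from pathlib import Path

from .biophysics import GateKinetics, IonEnvironment, NeuronParameters, RectifierKinetics
from .network import NetworkSpec

__all__ = ["to_config", "from_config", "save_config", "load_config", "defaults_text"]

_KIN_FIELDS = ("x_half", "k_x", "tau_max", "tau_half", "k_tau")
_RECT_FIELDS = ("A_alpha", "B_alpha", "k_alpha", "A_beta", "B_beta", "k_beta")


def to_config(neuron: NeuronParameters | None = None,
              env: IonEnvironment | None = None,
              network: NetworkSpec | None = None) -> str:
    """Serialize parameter objects to flat ``key = value`` text."""
    lines = []
    if neuron is not None:
        for f in fields(neuron):
            v = getattr(neuron, f.name)
            if isinstance(v, GateKinetics):
                for kf in _KIN_FIELDS:
                    lines.append(f"neuron.{f.name}.{kf} = {getattr(v, kf)!r}")
            elif isinstance(v, RectifierKinetics):
                for kf in _RECT_FIELDS:
                    lines.append(f"neuron.{f.name}.{kf} = {getattr(v, kf)!r}")
            else:
                lines.append(f"neuron.{f.name} = {v!r}")
    if env is not None:
        for f in fields(env):
            lines.append(f"env.{f.name} = {getattr(env, f.name)!r}")
    if network is not None:
        for f in fields(network):
            lines.append(f"network.{f.name} = {getattr(network, f.name)!r}")
    return "\n".join(lines) + "\n"


def _parse(text: str) -> dict:
    out = {}
    for ln, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"line {ln}: expected 'key = value', got {raw!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        try:
            out[key] = eval(val, {"__builtins__": {}}, {})  # literals only
        except Exception as exc:
            raise ValueError(f"line {ln}: cannot parse value {val!r}") from exc
    return out


def from_config(text: str) -> dict:
    """Parse config text into ``{"neuron": ..., "env": ..., "network": ...}``.

    Sections absent from the text are returned as the corresponding defaults.
    """
    kv = _parse(text)
    neuron_kw: dict = {}
    env_kw: dict = {}
    net_kw: dict = {}
    kin_kw: dict = {}
    for key, val in kv.items():
        parts = key.split(".")
        if parts[0] == "neuron" and len(parts) == 3:
            kin_kw.setdefault(parts[1], {})[parts[2]] = val
        elif parts[0] == "neuron" and len(parts) == 2:
            neuron_kw[parts[1]] = val
        elif parts[0] == "env" and len(parts) == 2:
            env_kw[parts[1]] = val
        elif parts[0] == "network" and len(parts) == 2:
            net_kw[parts[1]] = val
        else:
            raise ValueError(f"unknown config key {key!r}")
    base = NeuronParameters()
    for name, kw in kin_kw.items():
        current = getattr(base, name)
        cls = RectifierKinetics if isinstance(current, RectifierKinetics) else GateKinetics
        neuron_kw[name] = cls(**{**{f: getattr(current, f) for f in
                                    (_RECT_FIELDS if cls is RectifierKinetics else _KIN_FIELDS)},
                                 **kw})
    try:
        return {
            "neuron": replace(base, **neuron_kw),
            "env": IonEnvironment(**env_kw),
            "network": NetworkSpec(**net_kw),
        }
    except TypeError as exc:
        raise ValueError(f"unknown config key: {exc}") from exc


def save_config(path, **objects):
    Path(path).write_text(to_config(**objects))


def load_config(path) -> dict:
    return from_config(Path(path).read_text())


def defaults_text() -> str:
    """Text of the shipped default configuration."""
    return (resources.files("prebotc") / "data" / "defaults.cfg").read_text()
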
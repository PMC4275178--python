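"""Run configuration: serialization of stage configs and seed derivation."""

from __future__ import annotations

import dataclasses
import zlib
from pathlib import Path

import yaml

from .sim import Boundary, Kernel, RateSet, SimConfig

__all__ = ["derive_seed", "sim_config_to_dict", "sim_config_from_dict",
           "load_sim_config", "dump_sim_config"]


def derive_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed: crc32 of "<global_seed>:<stage>", masked to 31 bits.

    Documented, stable rule so every stage of a run is reproducible from
    the single global seed.
    """
    return zlib.crc32(f"{global_seed}:{stage}".encode()) & 0x7FFFFFFF


def sim_config_to_dict(cfg: SimConfig) -> dict:
    d = dataclasses.asdict(cfg)
    # callables are not serializable; record the response by name
    resp = cfg.rates.inhibitor_response
    d["rates"]["inhibitor_response"] = getattr(resp, "__name__", "custom")
    d["rates"]["kernel"] = {"weights": list(cfg.rates.kernel.weights)}
    d["locus_window"] = list(cfg.locus_window)
    return d


def sim_config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    rates_d = dict(d.pop("rates", {}))
    resp_name = rates_d.pop("inhibitor_response", "competitive_inhibition")
    if resp_name not in ("competitive_inhibition", "custom"):
        raise ValueError(f"unknown inhibitor response {resp_name!r}")
    kernel_d = rates_d.pop("kernel", None)
    kwargs = {}
    if kernel_d is not None:
        kwargs["kernel"] = Kernel(tuple(kernel_d["weights"]))
    if "methylation_targets" in rates_d:
        rates_d["methylation_targets"] = tuple(
            rates_d["methylation_targets"])
    rates = RateSet(**rates_d, **kwargs)
    boundary = Boundary(**d.pop("boundary", {}))
    if "locus_window" in d:
        d["locus_window"] = tuple(d["locus_window"])
    return SimConfig(rates=rates, boundary=boundary, **d)


def load_sim_config(path: str | Path) -> SimConfig:
    with open(path) as fh:
        return sim_config_from_dict(yaml.safe_load(fh) or {})


def dump_sim_config(cfg: SimConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(sim_config_to_dict(cfg), fh, sort_keys=False)
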
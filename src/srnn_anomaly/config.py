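"""Run configuration: one structured file covering every module.

The YAML layout has one section per module (``network``, ``plasticity``,
``encoding``, ``neuron``, ``synapse``, ``waveform``, ``readout``) plus the
global ``seed``.  Omitted sections and keys fall back to the reference
defaults (the simulation values shipped as ``REFERENCE_PROFILE``), so an
empty file is a valid config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version

import yaml

from .anomaly import PipelineConfig
from .coding import EncodingConfig
from .dynamics import NeuronParams, SynapseParams, calibrate_alpha
from .network import NetworkConfig
from .plasticity import PlasticityConfig
from .synthetic import WaveformSpec

__all__ = ["RunConfig", "REFERENCE_PROFILE"]


def _build(cls, data: dict, tuple_keys=()):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    data = dict(data)
    for k in tuple_keys:
        if k in data:
            data[k] = tuple(tuple(x) if isinstance(x, (list, tuple)) else x for x in data[k])
    return cls(**data)


@dataclass(frozen=True)
class RunConfig:
    """All module configs plus the global seed."""

    network: NetworkConfig = field(default_factory=NetworkConfig)
    plast: PlasticityConfig = field(default_factory=PlasticityConfig)
    encoding: EncodingConfig = field(default_factory=EncodingConfig)
    neuron: NeuronParams = field(default_factory=NeuronParams)
    synapse: SynapseParams | None = None
    waveform: WaveformSpec = field(default_factory=WaveformSpec)
    ridge: float = 1e-6
    epsilon: float = 0.05
    seed: int = 0

    def pipeline(self) -> PipelineConfig:
        return PipelineConfig(network=self.network, plast=self.plast,
                              encoding=self.encoding, neuron=self.neuron,
                              ridge=self.ridge, epsilon=self.epsilon)

    def resolved_synapse(self) -> SynapseParams:
        if self.synapse is not None:
            return self.synapse
        return SynapseParams(alpha=calibrate_alpha(params=self.neuron))

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "network": dataclasses.asdict(self.network),
            "plasticity": dataclasses.asdict(self.plast),
            "encoding": dataclasses.asdict(self.encoding),
            "neuron": dataclasses.asdict(self.neuron),
            "waveform": dataclasses.asdict(self.waveform),
            "readout": {"ridge": self.ridge, "epsilon": self.epsilon},
            "seed": self.seed,
        }
        if self.synapse is not None:
            d["synapse"] = dataclasses.asdict(self.synapse)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        readout = data.pop("readout", {})
        syn = data.pop("synapse", None)
        known = {"network", "plasticity", "encoding", "neuron", "waveform", "seed"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        return cls(
            network=_build(NetworkConfig, data.get("network", {})),
            plast=_build(PlasticityConfig, data.get("plasticity", {})),
            encoding=_build(EncodingConfig, data.get("encoding", {})),
            neuron=_build(NeuronParams, data.get("neuron", {})),
            synapse=_build(SynapseParams, syn) if syn is not None else None,
            waveform=_build(WaveformSpec, data.get("waveform", {}),
                            tuple_keys=("beat_shape", "anomaly_spec")),
            ridge=float(readout.get("ridge", 1e-6)),
            epsilon=float(readout.get("epsilon", 0.05)),
            seed=int(data.get("seed", 0)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    def provenance(self, seed: int | None = None) -> dict:
        try:
            ver = version("srnn-anomaly")
        except PackageNotFoundError:  # pragma: no cover
            ver = "unknown"
        return {"config_sha256": self.config_hash(),
                "seed": int(self.seed if seed is None else seed),
                "package_version": ver}


#: the shipped defaults as a plain dict (the reference parameter profile)
REFERENCE_PROFILE = RunConfig().to_dict()
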
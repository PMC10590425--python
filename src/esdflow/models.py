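"""Joint model bundle (encoder + TCN + attention head) and checkpointing.

A checkpoint is a single ``.npz`` archive holding every weight array plus a
JSON-encoded config/seed record, so a trained recognizer can be reloaded for
streaming inference with one call.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .attention import AttentionHead, HeadConfig
from .encoder import EncoderConfig, SpatialEncoder
from .tcn import TcnConfig, TemporalConvNet


@dataclass
class ModelBundle:
    """Pruned encoder + temporal fusion + attention head, ready for inference."""

    encoder: SpatialEncoder
    tcn: TemporalConvNet
    head: AttentionHead

    def __post_init__(self) -> None:
        validate_bundle_configs(
            self.encoder.config, self.tcn.config, self.head.config
        )

    def save(self, path: str | Path, extra: dict | None = None) -> None:
        meta = {
            "encoder_config": asdict(self.encoder.config),
            "tcn_config": asdict(self.tcn.config),
            "head_config": asdict(self.head.config),
            "pruned": self.encoder.pruned,
            "extra": extra or {},
        }
        arrays = {}
        arrays.update(self.encoder.state_arrays())
        arrays.update(self.tcn.state_arrays())
        arrays.update(self.head.state_arrays())
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "ModelBundle":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            arrays = {k: data[k] for k in data.files if k != "__meta__"}
        enc_cfg = meta["encoder_config"]
        for key in ("projection_dims", "input_hw"):
            enc_cfg[key] = tuple(enc_cfg[key])
        tcn_cfg = meta["tcn_config"]
        tcn_cfg["dilations"] = tuple(tcn_cfg["dilations"])
        encoder = SpatialEncoder(EncoderConfig(**enc_cfg))
        if meta["pruned"]:
            encoder.prune_heads()
        tcn = TemporalConvNet(TcnConfig(**tcn_cfg))
        head = AttentionHead(HeadConfig(**meta["head_config"]))
        encoder.load_state_arrays(arrays)
        tcn.load_state_arrays(arrays)
        head.load_state_arrays(arrays)
        return cls(encoder, tcn, head)


def validate_bundle_configs(
    enc: EncoderConfig, tcn: TcnConfig, head: HeadConfig
) -> None:
    """Dimensional consistency checks across the three modules."""
    if tcn.input_dim != enc.embedding_dim:
        raise ValueError(
            f"TCN input_dim {tcn.input_dim} != encoder embedding_dim "
            f"{enc.embedding_dim}"
        )
    if head.channels != tcn.channels:
        raise ValueError(
            f"head channels d'={head.channels} != TCN channels {tcn.channels}"
        )
    if head.query_dim != enc.embedding_dim:
        raise ValueError(
            f"head query_dim {head.query_dim} != encoder embedding_dim "
            f"{enc.embedding_dim}"
        )


def random_bundle(
    enc_config: EncoderConfig | None = None,
    tcn_config: TcnConfig | None = None,
    head_config: HeadConfig | None = None,
    seed: int = 0,
) -> ModelBundle:
    """An untrained, randomly initialized bundle (testing / benchmarking)."""
    enc_config = enc_config or EncoderConfig()
    tcn_config = tcn_config or TcnConfig(input_dim=enc_config.embedding_dim)
    head_config = head_config or HeadConfig(
        query_dim=enc_config.embedding_dim, channels=tcn_config.channels
    )
    rng = np.random.default_rng(seed)
    s1, s2, s3 = rng.integers(0, 2**31, size=3)
    encoder = SpatialEncoder(enc_config, int(s1))
    encoder.prune_heads()
    return ModelBundle(
        encoder, TemporalConvNet(tcn_config, int(s2)),
        AttentionHead(head_config, int(s3))
    )
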
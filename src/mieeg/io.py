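"""HDF5 trial/feature/model containers and the YAML run configuration.

Container layout (format_version "1"):

* ``/trials``  -- float array [n_trials x 2 x n_samples]
* ``/labels``  -- int vector, 0 = left, 1 = right (legend in an attribute)
* root attrs  -- sampling_rate_hz, channel_names, imagery_onset_s,
  imagery_duration_s, seed, format_version, generator_config (JSON)

Feature tensors go under ``/features/stft`` and ``/features/cwt`` with axis
attributes, CSP filters under ``/csp``, CNN parameters under ``/model``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import h5py
import numpy as np
import yaml

from .cnn import CNNArchitecture, CNNParameters, ConvSpec, TrainingConfig
from .csp import CSPFilterBlock, CSPModel
from .synth import CHANNELS, LABELS, GeneratorConfig, Trial, TrialSet
from .timefreq import FeatureTensor
from .train_eval import SplitSpec

FORMAT_VERSION = "1"


class FormatError(ValueError):
    """A container is missing a dataset/attribute or has the wrong version."""


def _config_to_json(config: GeneratorConfig) -> str:
    return json.dumps(dataclasses.asdict(config))


def _config_from_json(payload: str) -> GeneratorConfig:
    raw = json.loads(payload)
    for key in ("mu_band_hz", "beta_band_hz"):
        raw[key] = tuple(raw[key])
    return GeneratorConfig(**raw)


def write_trials(path, trials: TrialSet) -> None:
    """Write a TrialSet to the HDF5 container (lossless round trip)."""
    cfg = trials.config
    with h5py.File(path, "w") as f:
        f.create_dataset("trials", data=trials.to_array())
        f.create_dataset("labels", data=trials.labels)
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["sampling_rate_hz"] = cfg.sampling_rate_hz
        f.attrs["channel_names"] = list(CHANNELS)
        f.attrs["imagery_onset_s"] = cfg.imagery_onset_s
        f.attrs["imagery_duration_s"] = cfg.imagery_duration_s
        f.attrs["seed"] = cfg.seed
        f.attrs["label_legend"] = [f"{i}={lab}" for i, lab in enumerate(LABELS)]
        f.attrs["generator_config"] = _config_to_json(cfg)


def validate_container(f: h5py.File) -> None:
    """Schema check; raises FormatError naming the first offending field."""
    for dset in ("/trials", "/labels"):
        if dset.lstrip("/") not in f:
            raise FormatError(f"container is missing dataset {dset}")
    for attr in ("format_version", "sampling_rate_hz", "generator_config"):
        if attr not in f.attrs:
            raise FormatError(f"container is missing attribute {attr!r}")
    version = str(f.attrs["format_version"])
    if version != FORMAT_VERSION:
        raise FormatError(
            f"format_version {version!r} unsupported (expected {FORMAT_VERSION!r})"
        )
    if f["trials"].shape[0] != f["labels"].shape[0]:
        raise FormatError("/trials first dimension does not match /labels length")


def read_trials(path) -> TrialSet:
    """Read a TrialSet back from the HDF5 container."""
    with h5py.File(path, "r") as f:
        validate_container(f)
        config = _config_from_json(f.attrs["generator_config"])
        data = np.asarray(f["trials"])
        labels = np.asarray(f["labels"], dtype=int)
    trials = tuple(
        Trial(samples=data[i], label=LABELS[labels[i]]) for i in range(data.shape[0])
    )
    return TrialSet(trials=trials, config=config)


def write_feature_tensors(path, tensors: dict[str, list[FeatureTensor]],
                          labels: np.ndarray) -> None:
    """Write named per-trial feature tensors under /features/<name>."""
    with h5py.File(path, "a") as f:
        f.attrs.setdefault("format_version", FORMAT_VERSION)
        if "labels" not in f:
            f.create_dataset("labels", data=np.asarray(labels, dtype=int))
        grp = f.require_group("features")
        for name, tensor_list in tensors.items():
            if name in grp:
                del grp[name]
            stacked = np.stack([t.values for t in tensor_list], axis=0)
            ds = grp.create_dataset(name, data=stacked)
            first = tensor_list[0]
            ds.attrs["row_kind"] = first.row_kind
            ds.attrs["row_values"] = first.row_values
            ds.attrs["col_values"] = first.col_values
            ds.attrs["channel_names"] = list(first.channel_names)
            if first.pseudo_freqs_hz is not None:
                ds.attrs["pseudo_freqs_hz"] = first.pseudo_freqs_hz


def write_csp_model(path, model: CSPModel) -> None:
    with h5py.File(path, "a") as f:
        if "csp" in f:
            del f["csp"]
        grp = f.create_group("csp")
        grp.attrs["m"] = model.m
        grp.attrs["sampling_rate_hz"] = model.sampling_rate_hz
        grp.attrs["bands"] = np.asarray(model.bands)
        for i, block in enumerate(model.blocks):
            sub = grp.create_group(f"band{i}")
            sub.create_dataset("filters", data=block.filters)
            sub.create_dataset("eigenvalues", data=block.eigenvalues)
            sub.attrs["band"] = np.asarray(block.band)
            sub.attrs["m"] = block.m


def read_csp_model(path) -> CSPModel:
    with h5py.File(path, "r") as f:
        if "csp" not in f:
            raise FormatError("container is missing group /csp")
        grp = f["csp"]
        blocks = []
        for i in range(len(grp.attrs["bands"])):
            sub = grp[f"band{i}"]
            blocks.append(CSPFilterBlock(
                filters=np.asarray(sub["filters"]),
                eigenvalues=np.asarray(sub["eigenvalues"]),
                band=tuple(sub.attrs["band"]),
                m=int(sub.attrs["m"]),
            ))
        return CSPModel(blocks=tuple(blocks),
                        sampling_rate_hz=float(grp.attrs["sampling_rate_hz"]))


def write_cnn(path, params: CNNParameters, arch: CNNArchitecture) -> None:
    with h5py.File(path, "a") as f:
        if "model" in f:
            del f["model"]
        grp = f.create_group("model")
        grp.attrs["architecture"] = json.dumps({
            "input_length": arch.input_length,
            "conv_layers": [[c.n_kernels, c.kernel_length] for c in arch.conv_layers],
            "dense_width": arch.dense_width,
            "n_classes": arch.n_classes,
        })
        for i, (k, b) in enumerate(zip(params.conv_kernels, params.conv_biases)):
            grp.create_dataset(f"conv{i}_kernels", data=k)
            grp.create_dataset(f"conv{i}_bias", data=b)
        grp.create_dataset("dense_w", data=params.dense_w)
        grp.create_dataset("dense_b", data=params.dense_b)
        grp.create_dataset("out_w", data=params.out_w)
        grp.create_dataset("out_b", data=params.out_b)


def read_cnn(path) -> tuple[CNNParameters, CNNArchitecture]:
    with h5py.File(path, "r") as f:
        if "model" not in f:
            raise FormatError("container is missing group /model")
        grp = f["model"]
        spec = json.loads(grp.attrs["architecture"])
        arch = CNNArchitecture(
            input_length=spec["input_length"],
            conv_layers=tuple(ConvSpec(*c) for c in spec["conv_layers"]),
            dense_width=spec["dense_width"], n_classes=spec["n_classes"],
        )
        params = CNNParameters(
            conv_kernels=[np.asarray(grp[f"conv{i}_kernels"])
                          for i in range(len(arch.conv_layers))],
            conv_biases=[np.asarray(grp[f"conv{i}_bias"])
                         for i in range(len(arch.conv_layers))],
            dense_w=np.asarray(grp["dense_w"]), dense_b=np.asarray(grp["dense_b"]),
            out_w=np.asarray(grp["out_w"]), out_b=np.asarray(grp["out_b"]),
        )
        return params, arch


# ---------------------------------------------------------------------------
# Run configuration

_KNOWN_SECTIONS = {
    "generator": set(GeneratorConfig.__dataclass_fields__),
    "feature": {"kind"},
    "architecture": {"conv_layers", "dense_width"},
    "training": set(TrainingConfig.__dataclass_fields__) | {"max_iterations", "log_every"},
    "split": set(SplitSpec.__dataclass_fields__),
    "experiment": {"n_per_class", "m"},
}


@dataclass
class RunConfig:
    """Validated run configuration assembled from a YAML document."""

    generator: GeneratorConfig
    feature: str  # "stft" | "cwt" | "csp"
    conv_layers: tuple[tuple[int, int], ...] | None
    dense_width: int | None
    training: TrainingConfig
    max_iterations: int | None
    log_every: int
    split: SplitSpec
    n_per_class: int
    m: int


def load_run_config(path=None, *, seed: int | None = None) -> RunConfig:
    """Load a YAML run config; unknown sections or keys are rejected.

    ``seed`` (e.g. from a --seed flag) overrides every seed in the document.
    """
    doc = {}
    if path is not None:
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise FormatError("run config must be a mapping of sections")
    for section, payload in doc.items():
        if section not in _KNOWN_SECTIONS:
            raise FormatError(f"unknown config section {section!r}")
        payload = payload or {}
        if section == "feature":
            if not isinstance(payload, str):
                raise FormatError("'feature' must be a string (stft|cwt|csp)")
            continue
        unknown = set(payload) - _KNOWN_SECTIONS[section]
        if unknown:
            raise FormatError(
                f"unknown keys in section {section!r}: {sorted(unknown)}"
            )

    gen_kwargs = dict(doc.get("generator", {}))
    for key in ("mu_band_hz", "beta_band_hz"):
        if key in gen_kwargs:
            gen_kwargs[key] = tuple(gen_kwargs[key])
    train_kwargs = dict(doc.get("training", {}))
    max_iterations = train_kwargs.pop("max_iterations", None)
    log_every = train_kwargs.pop("log_every", 100)
    split_kwargs = dict(doc.get("split", {}))
    if seed is not None:
        gen_kwargs["seed"] = seed
        train_kwargs["seed"] = seed
        split_kwargs["seed"] = seed
    arch_section = doc.get("architecture", {}) or {}
    conv_layers = arch_section.get("conv_layers")
    if conv_layers is not None:
        conv_layers = tuple(tuple(int(v) for v in c) for c in conv_layers)
    experiment = doc.get("experiment", {}) or {}
    feature = doc.get("feature", "csp")
    if feature not in ("stft", "cwt", "csp"):
        raise FormatError(f"feature must be stft, cwt or csp, got {feature!r}")
    return RunConfig(
        generator=GeneratorConfig(**gen_kwargs),
        feature=feature,
        conv_layers=conv_layers,
        dense_width=arch_section.get("dense_width"),
        training=TrainingConfig(**train_kwargs),
        max_iterations=max_iterations,
        log_every=int(log_every),
        split=SplitSpec(**split_kwargs),
        n_per_class=int(experiment.get("n_per_class", 140)),
        m=int(experiment.get("m", 1)),
    )
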
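"""Deterministic generator of synthetic single-read FAST5 datasets.

The simulator emulates what a MinION run deposits on disk — one FAST5 per
read, with embedded FASTQ basecalls, event tables and channel/run metadata
— under fully known ground truth, so every downstream statistic can be
checked against an independent recomputation or a closed-form expectation.

Generative model (all draws from one seeded NumPy generator):

* read lengths ~ log-normal(median, sigma) rounded, truncated to
  ``[1, max_length]``;
* bases i.i.d. with ``P(G) = P(C) = gc_fraction/2`` and
  ``P(A) = P(T) = (1 - gc_fraction)/2``;
* per-base Phred quality ~ Normal(q0 + slope·pos/1000, sd), clipped to
  [0, 40] and rounded — a linear along-read decay profile;
* channel uniform over ``1..n_channels``; read start uniform over the run
  duration;
* every read has a template; a complement is present with probability
  ``p_complement`` and, given a complement, a 2D read with probability
  ``p_2d`` (2D basecalls require both strands);
* ``round(events_per_base · length)`` events per basecalled strand, with
  log-normal durations and Gaussian current levels around a per-k-mer mean.

The 2D sequence is drawn independently rather than by strand consensus:
downstream statistics never compare strands, so pairing fidelity is not
modeled.  Identical config + seed reproduces the dataset byte-for-byte.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import norm

from .fast5 import (
    BasecalledRead,
    ChannelInfo,
    EventRecord,
    Fast5Record,
    TrackingInfo,
    write_fast5,
)

__all__ = ["SimulationConfig", "generate_dataset", "expected_summary"]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of the synthetic FAST5 generator.

    Defaults describe a small early-chemistry MinION run: ~1 kb median
    reads with a long log-normal tail, balanced GC, mean Phred ≈ 12 at the
    read start decaying 1 Phred per kb, a 512-channel flowcell, and 2D
    chemistry succeeding for about a third of reads (0.7 × 0.5).
    """

    n_reads: int = 100
    length_median: float = 1000.0     # nt, median of the log-normal
    length_sigma: float = 0.5         # log-space sigma
    max_length: int = 50_000          # truncation bound, nt
    gc_fraction: float = 0.5
    q0: float = 12.0                  # mean Phred at position 0
    quality_slope: float = -1.0       # Phred change per kb along the read
    quality_sd: float = 2.0           # per-base Gaussian noise, Phred units
    n_channels: int = 512
    run_duration: float = 3600.0      # seconds
    run_id: str = "sim_run_000"
    exp_start_time: int = 1_400_000_000
    p_complement: float = 0.7
    p_2d: float = 0.5                 # conditional on complement presence
    events_per_base: float = 1.5
    uncalled_fraction: float = 0.0    # reads written with no basecalls
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gc_fraction", "p_complement", "p_2d", "uncalled_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.events_per_base <= 0:
            raise ValueError("events_per_base must be positive")

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "SimulationConfig":
        """Load a config from JSON or ``key=value`` lines."""
        text = Path(path).read_text()
        try:
            raw = json.loads(text)
        except json.JSONDecodeError:
            raw = {}
            for line in text.splitlines():
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                k, _, v = line.partition("=")
                raw[k.strip()] = v.strip()
        fields = {f: t for f, t in cls.__annotations__.items()}
        kwargs = {}
        for k, v in raw.items():
            if k not in fields:
                raise ValueError(f"unknown simulation parameter {k!r}")
            target = {int: int, float: float, str: str}.get(
                {"n_reads": int, "max_length": int, "n_channels": int,
                 "exp_start_time": int, "seed": int,
                 "run_id": str}.get(k, float), float
            )
            kwargs[k] = str(v) if k == "run_id" else target(v)
        return cls(**kwargs)


@dataclass(frozen=True)
class ManifestEntry:
    """Ground truth for one generated read."""

    name: str
    filename: str
    channel: int
    start_time: float                       # seconds since exp_start_time
    read_types: tuple[str, ...]
    sequences: dict[str, str] = field(default_factory=dict)
    qualities: dict[str, str] = field(default_factory=dict)
    uncalled: bool = False


def _draw_length(rng: np.random.Generator, cfg: SimulationConfig) -> int:
    ln = rng.lognormal(mean=np.log(cfg.length_median), sigma=cfg.length_sigma)
    return int(np.clip(round(ln), 1, cfg.max_length))


def _draw_sequence(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


def _draw_qualities(rng: np.random.Generator, n: int, cfg: SimulationConfig) -> str:
    pos = np.arange(n)
    q = cfg.q0 + cfg.quality_slope * pos / 1000.0 + rng.normal(0, cfg.quality_sd, n)
    q = np.clip(np.rint(q), 0, 40).astype(np.int64)
    return "".join(chr(33 + int(v)) for v in q)


def _draw_events(
    rng: np.random.Generator, sequence: str, cfg: SimulationConfig
) -> list[EventRecord]:
    n_events = int(round(cfg.events_per_base * len(sequence)))
    if n_events == 0:
        return []
    durations = rng.lognormal(mean=np.log(0.01), sigma=0.3, size=n_events)
    starts = np.concatenate([[0.0], np.cumsum(durations[:-1])])
    means = rng.normal(60.0, 8.0, size=n_events)
    stdvs = np.abs(rng.normal(1.0, 0.3, size=n_events))
    k = 5
    padded = sequence + "A" * k
    out = []
    for i in range(n_events):
        base_i = min(int(i / cfg.events_per_base), len(sequence) - 1)
        out.append(
            EventRecord(
                mean=float(means[i]),
                stdv=float(stdvs[i]),
                start=float(starts[i]),
                length=float(durations[i]),
                model_state=padded[base_i : base_i + k],
                move=int(rng.integers(0, 2)),
            )
        )
    return out


def generate_dataset(
    config: SimulationConfig, out_folder: str | os.PathLike
) -> list[ManifestEntry]:
    """Write ``config.n_reads`` FAST5 files and return the ground-truth manifest.

    File names are ``read_<i>_ch<channel>.fast5`` with a zero-padded index,
    so directory order matches generation order.  A ``manifest.json`` twin
    of the returned manifest is written alongside the files.
    """
    rng = np.random.default_rng(config.seed)
    out = Path(out_folder)
    out.mkdir(parents=True, exist_ok=True)
    tracking = TrackingInfo(
        run_id=config.run_id,
        exp_start_time=config.exp_start_time,
        flow_cell_id="FC_SIM",
        device_id="SIM01",
    )
    width = max(4, len(str(max(config.n_reads - 1, 0))))
    manifest: list[ManifestEntry] = []
    for i in range(config.n_reads):
        channel = int(rng.integers(1, config.n_channels + 1))
        # drawn in whole samples (5 kHz) so the stored start time is exact
        rate = 5000.0
        start_time = float(rng.integers(0, int(config.run_duration * rate))) / rate
        name = f"{config.run_id}_read_{i:0{width}d}"
        filename = f"read_{i:0{width}d}_ch{channel}.fast5"
        uncalled = bool(rng.random() < config.uncalled_fraction)

        reads: dict[str, BasecalledRead] = {}
        events: dict[str, list[EventRecord]] = {}
        if not uncalled:
            types = ["template"]
            if rng.random() < config.p_complement:
                types.append("complement")
                if rng.random() < config.p_2d:
                    types.append("2d")
            for rt in types:
                n = _draw_length(rng, config)
                seq = _draw_sequence(rng, n, config.gc_fraction)
                qual = _draw_qualities(rng, n, config)
                reads[rt] = BasecalledRead(rt, f"{name}_{rt}", seq, qual)
                events[rt] = _draw_events(rng, seq, config)

        record = Fast5Record(
            source_key=filename,
            tracking=tracking,
            channel=ChannelInfo(channel_number=channel),
            read_start_time=start_time,
            reads=reads,
            events=events,
            uncalled=uncalled,
        )
        write_fast5(record, out / filename)
        manifest.append(
            ManifestEntry(
                name=name,
                filename=filename,
                channel=channel,
                start_time=record.read_start_time,
                read_types=tuple(reads),
                sequences={rt: r.sequence for rt, r in reads.items()},
                qualities={rt: r.qualities for rt, r in reads.items()},
                uncalled=uncalled,
            )
        )
    (out / "manifest.json").write_text(
        json.dumps([asdict(m) for m in manifest], indent=0)
    )
    return manifest


def _truncated_lognormal_moments(cfg: SimulationConfig) -> tuple[float, float]:
    """Mean and variance of the truncated (not rounded) length law."""
    mu, s = np.log(cfg.length_median), cfg.length_sigma
    lo, hi = np.log(1.0), np.log(cfg.max_length)
    a, b = (lo - mu) / s, (hi - mu) / s
    z = norm.cdf(b) - norm.cdf(a)
    m1 = np.exp(mu + s**2 / 2) * (norm.cdf(b - s) - norm.cdf(a - s)) / z
    m2 = np.exp(2 * mu + 2 * s**2) * (norm.cdf(b - 2 * s) - norm.cdf(a - 2 * s)) / z
    return float(m1), float(m2 - m1**2)


def expected_summary(config: SimulationConfig) -> dict:
    """Closed-form expectations (with standard errors) under the generator.

    Used as recovery targets: pooled %GC, mean read quality, mean read
    length and total yield, each with the standard error implied by the
    sampling design.  Quality expectations ignore the [0, 40] clipping,
    which is negligible for profiles a few sd inside the bounds.
    """
    mean_len, var_len = _truncated_lognormal_moments(config)
    n = max(config.n_reads, 1)
    g = config.gc_fraction
    # per-read mean quality: mean over positions of q0 + slope*pos/1000
    # ~= q0 + slope*(L-1)/2000; averaged over the length law.
    mean_quality = config.q0 + config.quality_slope * (mean_len - 1) / 2000.0
    var_quality_between = (config.quality_slope / 2000.0) ** 2 * var_len
    var_quality_within = config.quality_sd**2 / max(mean_len, 1.0)
    return {
        "mean_length": mean_len,
        "mean_length_se": float(np.sqrt(var_len / n)),
        "gc_percent": 100.0 * g,
        "gc_percent_se": 100.0 * float(np.sqrt(g * (1 - g) / (n * mean_len))),
        "mean_quality": mean_quality,
        "mean_quality_se": float(
            np.sqrt((var_quality_between + var_quality_within) / n)
        ),
        "quality_slope_per_kb": config.quality_slope,
        "expected_yield": n * mean_len,
    }
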
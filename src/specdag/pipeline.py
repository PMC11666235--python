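"""End-to-end orchestration: simulate -> reduce -> CSD -> GC/DAI -> statistics.

A single :class:`RunConfig` drives the whole pipeline on a synthetic cohort
with known ground truth. One global seed fans out to per-stage substreams by
stable hashing of stage names, so each stage is reproducible independent of
execution order; every output file is accompanied by a MANIFEST recording the
config hash and seed. All tabular outputs are TSV with a fixed float format,
so repeated runs with the same seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coupling import correlate_connectivity_coupling, parcel_envelope_mi
from .granger import all_pairs_gc
from .reduction import reduce_parcels
from .spectral import multitaper_csd, segment
from .stats import DEFAULT_BANDS, BandDefinition, band_summary, dai_group_test, node_strength
from .synthetic import (
    Edge,
    NetworkSpec,
    ParticipantCohort,
    make_cohort,
    make_envelope_driven_parcel,
)

__all__ = ["RunConfig", "run_pipeline", "derive_seed"]

_FLOAT_FMT = "%.10g"


def derive_seed(master: int, stage: str) -> int:
    """Stable per-stage substream seed (< 2^31) from the global seed."""
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """All pipeline parameters. Validated up front, before any computation."""

    seed: int = 0
    # cohort
    n_participants: int = 12
    between_participant_sd: float = 0.1
    n_parcels: int = 2
    components_per_parcel: int = 3
    conditions: dict = field(
        default_factory=lambda: {
            "speaking": [
                {"source": 0, "target": 1, "strength": 0.25, "f0_hz": 10.0, "bw_hz": 6.0}
            ]
        }
    )
    noise_scale: float = 1.0
    fs: float = 256.0
    trial_length_s: float = 60.0
    n_trials: int = 1
    # spectral estimation
    win_s: float = 4.0
    overlap_s: float = 0.5
    smoothing_hz: float = 2.0
    k_components: int | None = None  # None: keep simulated components as-is
    # connectivity / statistics
    fmax: float = 100.0
    bands: list | None = None  # list of [name, f_low, f_high]; None = canonical set
    n_perm: int = 5000
    alpha: float = 0.05
    cluster_alpha: float = 0.05
    # envelope-coupling stage (optional)
    coupling_enabled: bool = False
    coupling_target: int = 0          # parcel receiving the envelope
    coupling_band: tuple = ("theta", 4.0, 8.0)
    lag_ms: float = 130.0
    envelope_snr: float = 1.0

    def validate(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if not 0 < self.cluster_alpha <= 1:
            raise ValueError(f"cluster_alpha must be in (0, 1], got {self.cluster_alpha}")
        if not 0 <= self.overlap_s < self.win_s:
            raise ValueError("need 0 <= overlap_s < win_s")
        if self.win_s > self.trial_length_s:
            raise ValueError("win_s exceeds trial length")
        if self.win_s * self.smoothing_hz < 1:
            raise ValueError("smoothing_hz * win_s must be >= 1 (at least one taper)")
        if self.n_perm < 1:
            raise ValueError("n_perm must be positive")
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")
        if self.fmax > self.fs / 2:
            raise ValueError("fmax exceeds Nyquist")
        if self.coupling_enabled:
            if self.lag_ms < 0 or self.lag_ms / 1000.0 >= self.trial_length_s:
                raise ValueError("lag_ms must be >= 0 and shorter than a trial")
            if not 0 <= self.coupling_target < self.n_parcels:
                raise ValueError("coupling_target must be a parcel index")
            if self.n_participants < 5:
                raise ValueError("coupling correlation needs at least 5 participants")
        # building the specs validates edges, Nyquist and stability
        for spec in self._network_specs().values():
            spec.check_stable()

    def _network_specs(self) -> dict:
        out = {}
        for cond, edges in self.conditions.items():
            out[cond] = NetworkSpec(
                n_parcels=self.n_parcels,
                components_per_parcel=self.components_per_parcel,
                edges=tuple(Edge(**e) for e in edges),
                noise_scale=self.noise_scale,
                fs=self.fs,
                trial_length_s=self.trial_length_s,
                n_trials=self.n_trials,
                seed=self.seed,
            )
        return out

    def band_definitions(self):
        if self.bands is None:
            return DEFAULT_BANDS
        return tuple(BandDefinition(str(n), float(lo), float(hi)) for n, lo, hi in self.bands)

    def config_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run every stage and write stage outputs plus a summary report.

    Returns a dict with the in-memory results (cohort truth table, DAI stack,
    cluster results, per-band edges, node strengths, output paths).
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    coupling_out = None
    manifest = {
        "package": "specdag",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": [],
    }
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)

    def _checkpoint():
        with open(outdir / "MANIFEST.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    try:
        # --- simulate ------------------------------------------------------
        specs = config._network_specs()
        base = next(iter(specs.values()))
        cohort = ParticipantCohort(
            base=base,
            n_participants=config.n_participants,
            between_participant_sd=config.between_participant_sd,
            conditions={c: s.edges for c, s in specs.items()},
            seed=derive_seed(config.seed, "simulate"),
        )
        data = make_cohort(cohort)
        _write_tsv(data.truth, outdir / "truth_edges.tsv")
        manifest["stages"].append("simulate")
        _checkpoint()

        # --- spectral + connectivity --------------------------------------
        conditions = list(config.conditions)
        dai_stacks: dict = {}
        gc_frames = []
        pairs = freqs = None
        for cond in conditions:
            per_part = []
            for i in range(config.n_participants):
                es = data.epochs[(i, cond)]
                epochs = segment(es, config.win_s, config.overlap_s)
                if config.k_components is not None:
                    epochs, _ = reduce_parcels(epochs, k=config.k_components)
                csd = multitaper_csd(epochs, config.smoothing_hz)
                gcs = all_pairs_gc(csd, fmax=config.fmax)
                pairs, freqs = gcs.pairs, gcs.freqs
                per_part.append(gcs.dai)
                gc_frames.append(gcs.to_frame(participant=i, condition=cond))
            dai_stacks[cond] = np.stack(per_part)
        _write_tsv(pd.concat(gc_frames, ignore_index=True), outdir / "gc_dai.tsv")
        manifest["stages"].append("connectivity")
        _checkpoint()

        # --- group statistics ----------------------------------------------
        bands = config.band_definitions()
        rng = np.random.default_rng(derive_seed(config.seed, "stats"))
        results = {}
        contrasts = {c: ("vs_zero", dai_stacks[c], None) for c in conditions}
        if len(conditions) == 2:
            contrasts[f"{conditions[0]}_vs_{conditions[1]}"] = (
                "between_conditions",
                dai_stacks[conditions[0]],
                dai_stacks[conditions[1]],
            )
        summary = {"config_hash": manifest["config_hash"], "seed": config.seed, "contrasts": {}}
        for label, (kind, d1, d2) in contrasts.items():
            res = dai_group_test(
                d1,
                freqs,
                pairs=pairs,
                contrast=kind,
                dai2=d2,
                bands=bands,
                n_perm=config.n_perm,
                alpha=config.alpha,
                cluster_alpha=config.cluster_alpha,
                rng=rng,
            )
            edges = band_summary(res, bands=bands)
            strength = node_strength(edges)
            results[label] = {"clusters": res, "edges": edges, "node_strength": strength}
            _write_tsv(edges, outdir / f"edges_{label}.tsv")
            _write_tsv(strength, outdir / f"node_strength_{label}.tsv")
            cl = pd.DataFrame(
                [
                    {
                        "band": c.band,
                        "parcel_a": c.pair[0],
                        "parcel_b": c.pair[1],
                        "f_low": float(freqs[c.bin_indices[0]]),
                        "f_high": float(freqs[c.bin_indices[-1]]),
                        "mass": c.mass,
                        "sign": c.sign,
                        "p": c.p,
                    }
                    for c in res.clusters
                ],
                columns=["band", "parcel_a", "parcel_b", "f_low", "f_high", "mass", "sign", "p"],
            )
            _write_tsv(cl, outdir / f"clusters_{label}.tsv")
            summary["contrasts"][label] = {
                "n_significant_clusters": len(res.significant()),
                "significant_edges": edges.to_dict(orient="records"),
            }
        manifest["stages"].append("stats")
        _checkpoint()

        # --- envelope coupling (optional) ----------------------------------
        if config.coupling_enabled:
            band = BandDefinition(
                str(config.coupling_band[0]),
                float(config.coupling_band[1]),
                float(config.coupling_band[2]),
            )
            cond0 = conditions[0]
            tgt_label = f"P{config.coupling_target}"
            rng_c = np.random.default_rng(derive_seed(config.seed, "coupling"))
            mi_vals = np.empty(config.n_participants)
            dai_rows, parcel_labels = [], None
            for i in range(config.n_participants):
                es, env = make_envelope_driven_parcel(
                    data.specs[(i, cond0)],
                    lag_ms=config.lag_ms,
                    snr=config.envelope_snr,
                    drive_parcel=config.coupling_target,
                    rng=rng_c,
                )
                epochs = segment(es, config.win_s, config.overlap_s)
                if config.k_components is not None:
                    epochs, _ = reduce_parcels(epochs, k=config.k_components)
                csd_i = multitaper_csd(epochs, config.smoothing_hz)
                gcs_i = all_pairs_gc(csd_i, fmax=config.fmax)
                tb = band.bins(gcs_i.freqs)
                cols, labels = [], []
                for j, (a, b) in enumerate(gcs_i.pairs):
                    # orient DAI toward the target parcel
                    if b == tgt_label:
                        cols.append(float(np.nanmean(gcs_i.dai[j, tb])))
                        labels.append(a)
                    elif a == tgt_label:
                        cols.append(-float(np.nanmean(gcs_i.dai[j, tb])))
                        labels.append(b)
                dai_rows.append(cols)
                parcel_labels = labels
                pdata = es.data[:, es.channels_of(tgt_label), :]
                mi_vals[i] = parcel_envelope_mi(pdata, env, es.fs, band, lag_ms=config.lag_ms)
            corr = correlate_connectivity_coupling(
                np.array(dai_rows), mi_vals, parcels=parcel_labels,
                n_perm=config.n_perm, alpha=config.alpha,
                rng=derive_seed(config.seed, "coupling_perm"),
            )
            mi_df = pd.DataFrame(
                {
                    "participant": np.arange(config.n_participants),
                    "parcel": tgt_label,
                    "band": band.name,
                    "lag_ms": config.lag_ms,
                    "mi_nats": mi_vals,
                }
            )
            _write_tsv(mi_df, outdir / "coupling_mi.tsv")
            _write_tsv(corr, outdir / "coupling_correlation.tsv")
            summary["coupling"] = {
                "band": band.name,
                "target": tgt_label,
                "n_significant_parcels": int(corr["significant"].sum()),
            }
            coupling_out = {"mi": mi_df, "correlation": corr}
            manifest["stages"].append("coupling")

        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True, default=str)
        manifest["stages"].append("report")
        manifest["complete"] = True
        _checkpoint()
    except Exception:
        manifest["complete"] = False
        _checkpoint()
        raise

    return {
        "truth": data.truth,
        "dai": dai_stacks,
        "pairs": pairs,
        "freqs": freqs,
        "results": results,
        "coupling": coupling_out,
        "outdir": outdir,
    }
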
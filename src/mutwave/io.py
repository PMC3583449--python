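"""File formats, run configuration, and the end-to-end report pipeline.

Tab-separated values are the canonical interchange format: mutation tables
carry 1-based positions (chrom, pos, ref, alt, line_id); repeats arrive as
standard 0-based half-open BED; genomes as FASTA plus a YAML geometry config
(length, oric, ter sites, optional paths).  Minimal single-sample VCF is
accepted read-only as an alternative mutation encoding.  Every output file
carries a header comment with the tool version, the seed, and checksums of
the inputs, so a run is reproducible from its outputs alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .binning import (
    BinConfig,
    bin_features,
    bin_mutations,
    fold_replichores,
    replichore_correlation,
)
from .feature_stats import correlate_battery, predict_track, select_model
from .gaps import compute_gaps, exclude_repeat_gaps, exponential_test
from .genome import CoordinateError, GenomeSpec, MutationRecord, MutationSet
from .montecarlo import dispersion_test, pattern_chi2, simulate_null
from .wavelet import dwt_smooth

__all__ = [
    "RunConfig",
    "read_mutations",
    "write_mutations_tsv",
    "read_repeats_bed",
    "write_repeats_bed",
    "read_genome",
    "write_genome_fasta",
    "read_feature_table",
    "write_track_tsv",
    "run_report",
]

logger = logging.getLogger(__name__)

MUTATION_COLUMNS = ["chrom", "pos", "ref", "alt", "line_id"]


class InputError(ValueError):
    """Malformed or inconsistent input file."""


def _checksum(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:12]


def _header_lines(seed: int | None = None, inputs: dict[str, Path] | None = None) -> str:
    lines = [f"# mutwave {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    for name, path in (inputs or {}).items():
        lines.append(f"# input {name}: {Path(path).name} sha256:{_checksum(path)}")
    return "\n".join(lines) + "\n"


def read_genome(config_path: str | Path) -> GenomeSpec:
    """Load a genome from a YAML geometry config.

    Keys: ``name``, ``length``, ``oric`` (1-based), ``ter_sites`` (label ->
    1-based position), optional ``fasta`` and ``repeats_bed`` paths
    (relative paths resolve against the config file's directory).
    """
    config_path = Path(config_path)
    spec = yaml.safe_load(config_path.read_text())
    base = config_path.parent
    sequence = None
    if spec.get("fasta"):
        records = list(SeqIO.parse(base / spec["fasta"], "fasta"))
        if len(records) != 1:
            raise InputError(
                f"expected a single-chromosome FASTA, got {len(records)} records"
            )
        sequence = str(records[0].seq).upper()
    repeats: tuple = ()
    if spec.get("repeats_bed"):
        repeats = read_repeats_bed(base / spec["repeats_bed"])
    return GenomeSpec(
        name=spec.get("name", "chromosome"),
        length=int(spec["length"]),
        oric=int(spec["oric"]),
        ter_sites={k: int(v) for k, v in (spec.get("ter_sites") or {}).items()},
        repeats=repeats,
        sequence=sequence,
    )


def write_genome_fasta(genome: GenomeSpec, path: str | Path) -> None:
    if genome.sequence is None:
        raise ValueError("genome carries no sequence")
    rec = SeqRecord(Seq(genome.sequence), id=genome.name, description="")
    SeqIO.write([rec], str(path), "fasta")


def read_repeats_bed(path: str | Path) -> tuple[tuple[int, int], ...]:
    """Repeat intervals from BED (0-based half-open; extra columns ignored)."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
    )
    if df["chrom"].nunique() > 1:
        raise InputError("multi-contig BED not supported (single circular chromosome)")
    return tuple(sorted(zip(df["start"].astype(int), df["end"].astype(int))))


def write_repeats_bed(genome: GenomeSpec, path: str | Path) -> None:
    with open(path, "w") as fh:
        for start, end in genome.repeats:
            fh.write(f"{genome.name}\t{start}\t{end}\trepeat\n")


def _read_mutations_vcf(path: Path, genome: GenomeSpec) -> pd.DataFrame:
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        line_id = samples[0] if samples else "line1"
        for rec in vcf:
            if rec.alts is None:
                continue
            rows.append(
                {
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": rec.alts[0],
                    "line_id": line_id,
                }
            )
    return pd.DataFrame(rows, columns=MUTATION_COLUMNS)


def read_mutations(
    path: str | Path, genome: GenomeSpec, strict: bool = False
) -> MutationSet:
    """Read a mutation table (TSV with header, or minimal VCF).

    Positions are 1-based in both encodings and are converted to internal
    coordinates.  With a genome sequence available, each record's reference
    base is cross-checked; mismatches are reported as warnings, or raised
    when ``strict``.  Multi-contig input is an error.
    """
    path = Path(path)
    first = ""
    with open(path) as fh:
        first = fh.readline()
    if path.suffix == ".vcf" or first.startswith("##fileformat=VCF"):
        df = _read_mutations_vcf(path, genome)
    else:
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"line_id": str})
        missing = [c for c in MUTATION_COLUMNS if c not in df.columns]
        if missing:
            raise InputError(f"mutation table {path} lacks column(s) {missing}")
    chroms = df["chrom"].unique()
    if len(chroms) > 1:
        raise InputError(
            f"multi-contig input not supported: found {sorted(map(str, chroms))}"
        )
    records = []
    mismatches = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        pos1 = int(row.pos)
        if not (1 <= pos1 <= genome.length):
            raise CoordinateError(
                f"{path} row {i}: position {pos1} outside [1, {genome.length}]"
            )
        ref, alt = str(row.ref).upper(), str(row.alt).upper()
        if len(ref) != 1 or len(alt) != 1:
            raise InputError(
                f"{path} row {i}: only single-base substitutions supported "
                f"({ref}>{alt})"
            )
        if genome.sequence is not None and genome.sequence[pos1 - 1] != ref:
            mismatches.append((i, pos1, ref, genome.sequence[pos1 - 1]))
        records.append(
            MutationRecord(
                position=pos1 - 1,
                ref_base=ref,
                alt_base=alt,
                line_id=str(row.line_id),
            )
        )
    if mismatches:
        msg = (
            f"{len(mismatches)} reference-base mismatch(es) vs genome "
            f"sequence, first: row {mismatches[0][0]} pos {mismatches[0][1]} "
            f"table={mismatches[0][2]} genome={mismatches[0][3]}"
        )
        if strict:
            raise InputError(msg)
        logger.warning(msg)
    return MutationSet(genome, records)


def write_mutations_tsv(
    mutations: MutationSet, path: str | Path, seed: int | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(seed=seed))
        mutations.to_frame().to_csv(fh, sep="\t", index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Positional feature table: columns pos (1-based) or start/end, value."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "value" not in df.columns:
        raise InputError(f"feature table {path} lacks a 'value' column")
    return df


def load_feature_tracks(
    genome: GenomeSpec,
    feature_dir: str | Path,
    config: BinConfig,
    aggregation: str = "mean",
) -> list:
    """Binned feature tracks from a directory of TSVs.

    ``*.binned.tsv`` files are read as ready-made per-bin values (a 'value'
    column of length n_bins); other ``*.tsv`` files are positional tables
    aggregated through :func:`mutwave.binning.bin_features`.
    """
    from .binning import BinnedTrack

    tracks = []
    for fpath in sorted(Path(feature_dir).glob("*.tsv")):
        if fpath.name.endswith(".binned.tsv"):
            df = pd.read_csv(fpath, sep="\t", comment="#")
            if "value" not in df.columns:
                raise InputError(f"{fpath} lacks a 'value' column")
            tracks.append(
                BinnedTrack(
                    config,
                    df["value"].to_numpy(float),
                    "mean",
                    genome.length,
                    fpath.name.replace(".binned.tsv", ""),
                )
            )
        else:
            tracks.append(
                bin_features(
                    read_feature_table(fpath), genome, config,
                    aggregation=aggregation, name=fpath.stem,
                )
            )
    return tracks


def write_track_tsv(
    track, path: str | Path, seed: int | None = None, inputs: dict | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(seed=seed, inputs=inputs))
        track.to_frame().to_csv(fh, sep="\t", index=False)


@dataclass
class RunConfig:
    """Configuration for the end-to-end report pipeline."""

    genome_config: Path
    mutations: Path
    feature_dir: Path | None = None
    n_bins: int = 46
    offset_fraction: float = 0.0
    n_sims: int = 1000
    levels_zeroed: int = 2
    wavelet: str = "db4"
    max_terms: int = 5
    seed: int = 0
    out_dir: Path = Path("mutwave_report")
    feature_aggregation: str = "mean"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        base = Path(path).parent
        kwargs = dict(raw)
        for key in ("genome_config", "mutations", "feature_dir", "out_dir"):
            if kwargs.get(key) is not None:
                kwargs[key] = base / kwargs[key]
        return cls(**kwargs)


def run_report(config: RunConfig) -> dict:
    """Run the full pipeline: bin, fold, gaps, null, smooth, correlate, model.

    Writes per-stage TSVs plus a machine-readable ``summary.json`` into the
    output directory and returns the summary dict.  Deterministic given the
    seed.  Missing feature directory skips the correlation and regression
    stages with a logged notice.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = read_genome(config.genome_config)
    mutations = read_mutations(config.mutations, genome)
    bin_config = BinConfig(
        n_bins=config.n_bins, offset_fraction=config.offset_fraction
    )
    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "inputs": {
            "genome_config": _checksum(config.genome_config),
            "mutations": _checksum(config.mutations),
        },
        "n_mutations": len(mutations),
        "spectrum": mutations.spectrum.round(4).to_dict(),
    }

    track = bin_mutations(mutations, bin_config)
    write_track_tsv(track, out / "bins.tsv", seed=config.seed)
    fold = fold_replichores(track)
    corr = replichore_correlation(fold)
    summary["binning"] = {
        "n_bins": config.n_bins,
        "mean": float(track.values.mean()),
        "variance": float(track.values.var(ddof=1)),
    }
    summary["replichore"] = {
        "rho_pearson": corr.rho,
        "p_value": corr.p_value,
        "n_pairs": corr.n,
    }

    gapset = compute_gaps(mutations)
    excluded = exclude_repeat_gaps(gapset, genome.repeats)
    gap_test = exponential_test(excluded)
    pd.DataFrame({"gap_bp": excluded.gaps}).to_csv(
        out / "gaps.tsv", sep="\t", index=False
    )
    gap_test.qq_table.to_csv(out / "gaps_qq.tsv", sep="\t", index=False)
    summary["gaps"] = {
        "mean_gap_raw": gapset.mean_gap,
        "mean_gap_excluded": excluded.mean_gap,
        "n_retained": excluded.n_retained,
        "effective_length": excluded.effective_length,
        "chi2": gap_test.chi2,
        "df": gap_test.df,
        "p_value": gap_test.p_value,
    }

    disp = dispersion_test(track)
    summary["dispersion"] = {
        "mean": disp.mean,
        "variance": disp.variance,
        "statistic": disp.statistic,
        "df": disp.df,
        "p_value": disp.p_value,
    }
    ensemble = simulate_null(
        mutations, genome, n_sims=config.n_sims, config=bin_config, seed=config.seed
    )
    pd.DataFrame({"variance": ensemble.variances}).to_csv(
        out / "null_variances.tsv", sep="\t", index=False
    )
    null_summary = ensemble.variance_summary()
    null_summary["fraction_exceeding_observed"] = float(
        (ensemble.variances >= disp.variance).mean()
    )
    if np.all(track.values > 0):
        chi2s = [
            pattern_chi2(sim, track.values).chi2
            for sim in ensemble.counts[: min(100, ensemble.n_sims)]
        ]
        null_summary["min_pattern_chi2"] = float(np.min(chi2s))
    else:
        logger.info("empty observed bin(s): pattern chi-square skipped")
    summary["null"] = null_summary

    smooth = dwt_smooth(
        track.values, levels_zeroed=config.levels_zeroed, wavelet=config.wavelet
    )
    pd.DataFrame(
        {"bin": np.arange(1, config.n_bins + 1), "count": smooth.values,
         "smoothed": smooth.smoothed}
    ).to_csv(out / "smoothed.tsv", sep="\t", index=False)
    summary["wavelet"] = {
        "wavelet": config.wavelet,
        "levels_zeroed": config.levels_zeroed,
    }

    if config.feature_dir is not None and Path(config.feature_dir).is_dir():
        feature_tracks = load_feature_tracks(
            genome, config.feature_dir, bin_config,
            aggregation=config.feature_aggregation,
        )
        if feature_tracks:
            battery = correlate_battery(track, feature_tracks)
            battery.to_csv(out / "correlations.tsv", sep="\t", index=False)
            fit = select_model(track, feature_tracks, max_terms=config.max_terms)
            pred = predict_track(fit, {t.name: t for t in feature_tracks})
            write_track_tsv(pred, out / "predicted.tsv", seed=config.seed)
            summary["model"] = {
                "features": list(fit.features),
                "intercept": fit.intercept,
                "coefficients": fit.coefficients,
                "r_squared": fit.r_squared,
                "p_value": fit.p_value,
                "aic": fit.aic,
            }
            summary["correlations"] = battery.to_dict(orient="records")
    else:
        logger.info("no feature directory: correlation and regression skipped")

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
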
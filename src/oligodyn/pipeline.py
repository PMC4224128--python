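"""End-to-end orchestration and the cross-dataset core-taxon report.

``run_pipeline`` chains the stages — read preparation, family
classification, per-family entropy decomposition, observation-matrix
construction, oligotype taxonomy, and trajectory statistics — writing
every stage's output as TSV/JSON into one artifact directory.  Re-running
an identical configuration reproduces the outputs byte for byte (the run
log records parameters and library versions, never wall-clock state).

``core_taxa_report`` formalizes the characteristic-microbiota question:
a reference taxon is *core* in a dataset when some oligotype with mean
abundance of at least 0.5% is at least 98.5% identical to the taxon's
reference sequence; references that are themselves >= 98.5% identical are
merged into one group so near-duplicate references count once.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy
import yaml

from importlib.metadata import version as _pkg_version
from oligodyn.dynamics import (
    CorrelationConfig,
    autocorrelate,
    cross_correlate,
    detect_dominance_switch,
    interpolate_missing_days,
    periodogram,
)
from oligodyn.oligotyping import (
    DecompositionConfig,
    build_counts_matrix,
    collapse_reads,
    column_entropy,
    decompose_family,
    normalize_percent,
    oligotype_ids,
    oligotype_report,
)
from oligodyn.panel import ReferencePanel
from oligodyn.prep import PrepConfig, prepare, read_manifest, write_readset
from oligodyn.taxonomy import (
    TaxonomyConfig,
    assign_oligotype_taxonomy,
    best_window_identity,
    classify_reads_family,
)


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name for the abort message."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


@dataclass
class PipelineConfig:
    """Paths, stage parameters, core-taxon thresholds, and the global seed."""

    manifest: Path
    reference_panel: Path
    out_dir: Path
    prep: PrepConfig = field(default_factory=PrepConfig)
    decomposition: DecompositionConfig = field(default_factory=DecompositionConfig)
    taxonomy: TaxonomyConfig = field(default_factory=TaxonomyConfig)
    correlation: CorrelationConfig = field(default_factory=CorrelationConfig)
    core_identity: float = 98.5  # %, oligotype-to-reference match floor
    core_abundance: float = 0.5  # %, mean-abundance floor for a core oligotype
    dominance_threshold: float = 0.5
    min_persistence: int = 14
    acf_window: int = 21
    seed: int = 0

    def __post_init__(self) -> None:
        self.manifest = Path(self.manifest)
        self.reference_panel = Path(self.reference_panel)
        self.out_dir = Path(self.out_dir)
        for pct in (self.core_identity, self.core_abundance):
            if not (0.0 < pct <= 100.0):
                raise ValueError("core thresholds must be in (0, 100]")
        self.prep.seed = self.seed

    def validate_paths(self) -> None:
        for p in (self.manifest, self.reference_panel):
            if not p.exists():
                raise FileNotFoundError(f"configured path does not exist: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        paths = raw.get("paths", {})
        kwargs = dict(
            manifest=paths["manifest"],
            reference_panel=paths["reference_panel"],
            out_dir=paths.get("out_dir", "oligodyn_out"),
        )
        if "prep" in raw:
            kwargs["prep"] = PrepConfig(**raw["prep"])
        if "decomposition" in raw:
            kwargs["decomposition"] = DecompositionConfig(**raw["decomposition"])
        if "taxonomy" in raw:
            kwargs["taxonomy"] = TaxonomyConfig(**raw["taxonomy"])
        if "correlation" in raw:
            kwargs["correlation"] = CorrelationConfig(**raw["correlation"])
        for key in (
            "core_identity",
            "core_abundance",
            "dominance_threshold",
            "min_persistence",
            "acf_window",
            "seed",
        ):
            if key in raw.get("analysis", {}):
                kwargs[key] = raw["analysis"][key]
        return cls(**kwargs)


def _stage(name: str):
    def wrap(fn):
        def run(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - abort with stage context
                raise PipelineError(name, str(exc)) from exc

        return run

    return wrap


def classify_readset_families(
    reads_by_sample: dict[str, list[str]], panel: ReferencePanel
) -> tuple[dict[str, dict[str, list[str]]], pd.DataFrame]:
    """Split every sample's reads by assigned family.

    Classification runs once per unique sequence.  Returns
    (family -> sample -> reads, family × sample count table including an
    ``unassigned`` row).
    """
    unique: dict[str, None] = {}
    for reads in reads_by_sample.values():
        for r in reads:
            unique.setdefault(r, None)
    uniq_list = list(unique)
    labels = classify_reads_family(uniq_list, panel)
    label_of = dict(zip(uniq_list, labels))

    per_family: dict[str, dict[str, list[str]]] = {}
    count_rows: dict[str, dict[str, int]] = {}
    for sid, reads in reads_by_sample.items():
        for r in reads:
            fam = label_of[r] or "unassigned"
            if fam != "unassigned":
                per_family.setdefault(fam, {s: [] for s in reads_by_sample})
                per_family[fam][sid].append(r)
            count_rows.setdefault(fam, {})
            count_rows[fam][sid] = count_rows[fam].get(sid, 0) + 1
    counts = (
        pd.DataFrame(count_rows)
        .T.reindex(columns=list(reads_by_sample), fill_value=0)
        .fillna(0)
        .astype(int)
    )
    return per_family, counts


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage and write the artifact directory; returns its path."""
    config.validate_paths()
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)

    manifest = _stage("manifest")(read_manifest)(config.manifest)
    panel = _stage("reference_panel")(ReferencePanel.from_fasta)(config.reference_panel)

    readset, prep_report = _stage("prep")(prepare)(
        manifest, config.manifest.parent, config.prep
    )
    prep_report.to_csv(out / "prep_report.tsv", sep="\t", index=False)
    prepared_manifest = _stage("prep")(write_readset)(readset, manifest, out)
    manifest = read_manifest(prepared_manifest)

    per_family, family_counts = _stage("classify")(classify_readset_families)(
        readset.reads, panel
    )
    family_counts.rename_axis("family").to_csv(out / "family_counts.tsv", sep="\t")

    oligosets = []
    for fam in sorted(per_family):
        members, table = collapse_reads(per_family[fam])
        profile = column_entropy(members, table.sum(axis=1).to_numpy())
        pd.DataFrame(
            {"position": np.arange(1, len(profile) + 1), "entropy_bits": profile}
        ).to_csv(out / f"entropy_{fam}.tsv", sep="\t", index=False)
        oligosets.append(
            _stage("decompose")(decompose_family)(
                fam, per_family[fam], config.decomposition
            )
        )

    counts = _stage("matrices")(build_counts_matrix)(oligosets, manifest)
    percent, zero_cols = normalize_percent(counts)
    counts.rename_axis("oligotype_id").to_csv(out / "counts_matrix.tsv", sep="\t")
    percent.rename_axis("oligotype_id").to_csv(
        out / "percent_matrix.tsv", sep="\t", float_format="%.6f"
    )
    report = oligotype_report(oligosets)
    report.to_csv(out / "oligotype_report.tsv", sep="\t", index=False)

    tax_rows = []
    for row in report.itertuples():
        a = _stage("taxonomy")(assign_oligotype_taxonomy)(
            row.representative, panel, config.taxonomy, query_id=row.oligotype_id
        )
        tax_rows.append(
            {
                "oligotype_id": a.query_id,
                "percent_identity": round(a.percent_identity, 4),
                "status": a.status,
                "hits": ";".join(
                    f"{h.family}|{h.genus}|{h.species}|{h.taxon_id}" for h in a.best_hits
                ),
            }
        )
    pd.DataFrame(
        tax_rows,
        columns=["oligotype_id", "percent_identity", "status", "hits"],
    ).to_csv(out / "oligotype_taxonomy.tsv", sep="\t", index=False)

    _stage("dynamics")(_run_dynamics)(config, manifest, counts, percent, oligosets, out)

    log = {
        "oligodyn_version": _pkg_version("oligodyn"),
        "numpy_version": np.__version__,
        "scipy_version": scipy.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "config": {
            "prep": asdict(config.prep),
            "decomposition": asdict(config.decomposition),
            "taxonomy": asdict(config.taxonomy),
            "correlation": asdict(config.correlation),
            "core_identity": config.core_identity,
            "core_abundance": config.core_abundance,
            "dominance_threshold": config.dominance_threshold,
            "min_persistence": config.min_persistence,
            "acf_window": config.acf_window,
        },
        "n_samples": int(len(manifest)),
        "n_families": int(len(per_family)),
        "n_oligotypes": int(counts.shape[0]),
        "zero_total_samples": zero_cols,
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return out


def _run_dynamics(
    config: PipelineConfig,
    manifest: pd.DataFrame,
    counts: pd.DataFrame,
    percent: pd.DataFrame,
    oligosets,
    out: Path,
) -> None:
    if counts.shape[0] >= 2 and counts.shape[1] >= 3:
        basis = counts if config.correlation.data_basis == "counts" else percent
        corr = cross_correlate(basis, config.correlation)
        corr.to_csv(out / "correlations.tsv", sep="\t", index=False)

    days = manifest.set_index("sample_id")["day"]
    acf_rows, peri_rows = [], []
    daily = {}
    for oid in percent.index:
        obs_days = days[percent.columns].to_numpy()
        grid, vals = interpolate_missing_days(obs_days, percent.loc[oid].to_numpy())
        daily[oid] = (grid, vals)
        if len(grid) > config.acf_window:
            acf = autocorrelate(vals, window=config.acf_window)
            if not acf.constant:
                for lag, v in zip(acf.lags, acf.values):
                    acf_rows.append((oid, int(lag), v))
        if len(grid) >= 8:
            pg = periodogram(vals)
            peri_rows.append((oid, pg.peak_frequency, pg.peak_power_fraction))
    pd.DataFrame(acf_rows, columns=["oligotype_id", "lag", "acf"]).to_csv(
        out / "acf.tsv", sep="\t", index=False, float_format="%.6f"
    )
    pd.DataFrame(
        peri_rows, columns=["oligotype_id", "peak_frequency", "peak_power_fraction"]
    ).to_csv(out / "periodogram.tsv", sep="\t", index=False, float_format="%.6f")

    events = []
    for oset in oligosets:
        ids = [oid for oid, _ in oligotype_ids(oset)]
        if len(ids) < 2:
            continue
        grid = daily[ids[0]][0]
        shares = pd.DataFrame(
            {oid: daily[oid][1] for oid in ids}, index=grid
        ).T
        events.extend(
            detect_dominance_switch(
                shares,
                group_id=oset.family,
                min_persistence=config.min_persistence,
                dominance_threshold=config.dominance_threshold,
            )
        )
    pd.DataFrame(
        [(e.group_id, e.switch_day, e.from_id, e.to_id, e.persistence) for e in events],
        columns=["group_id", "switch_day", "from_id", "to_id", "persistence"],
    ).to_csv(out / "switch_events.tsv", sep="\t", index=False)


@dataclass
class DatasetSummary:
    """One dataset's percent matrix and oligotype representative sequences."""

    name: str
    percent: pd.DataFrame
    representatives: dict[str, str]  # oligotype id -> representative sequence


def _group_references(panel: ReferencePanel, identity: float) -> list[list[int]]:
    """Merge references that are pairwise >= identity%, by union-find."""
    n = len(panel)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    entries = list(panel)
    for i in range(n):
        for j in range(i + 1, n):
            if best_window_identity(entries[i].sequence, entries[j].sequence) >= identity:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return sorted(groups.values())


def core_taxa_report(
    datasets: Sequence[DatasetSummary],
    panel: ReferencePanel,
    identity_threshold: float = 98.5,
    abundance_threshold: float = 0.5,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Core-taxon table across datasets plus per-dataset coverage.

    A reference group is core in a dataset when some oligotype whose mean
    abundance reaches ``abundance_threshold`` (%) is at least
    ``identity_threshold`` % identical to a group member; its abundance in
    the dataset is the summed mean abundance of the oligotypes it best
    explains.  Coverage is the summed abundance of that dataset's core
    groups; groups core in every dataset are flagged as the consistent
    core.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    entries = list(panel)
    groups = _group_references(panel, identity_threshold)
    group_names = [
        "/".join(sorted({entries[i].species for i in grp})) for grp in groups
    ]

    rows = []
    coverage = {ds.name: 0.0 for ds in datasets}
    per_group_core: dict[int, dict[str, float | bool]] = {
        g: {} for g in range(len(groups))
    }
    for ds in datasets:
        mean_ab = ds.percent.mean(axis=1)
        abundant = [
            oid for oid in ds.percent.index if mean_ab[oid] >= abundance_threshold
        ]
        # best-matching group per abundant oligotype (no double counting)
        group_ab = {g: 0.0 for g in range(len(groups))}
        group_hit = {g: False for g in range(len(groups))}
        for oid in abundant:
            rep = ds.representatives.get(oid)
            if rep is None:
                continue
            idents = [
                max(best_window_identity(rep, entries[i].sequence) for i in grp)
                for grp in groups
            ]
            best_g = int(np.argmax(idents))
            if idents[best_g] >= identity_threshold:
                group_hit[best_g] = True
                group_ab[best_g] += float(mean_ab[oid])
        for g in range(len(groups)):
            per_group_core[g][f"core_in_{ds.name}"] = group_hit[g]
            per_group_core[g][f"abundance_{ds.name}"] = round(group_ab[g], 6)
            if group_hit[g]:
                coverage[ds.name] += group_ab[g]

    for g, grp in enumerate(groups):
        row = {
            "group": group_names[g],
            "members": ";".join(entries[i].name for i in grp),
            "taxon_ids": ";".join(sorted({entries[i].taxon_id for i in grp})),
        }
        row.update(per_group_core[g])
        row["consistent_core"] = all(
            per_group_core[g][f"core_in_{ds.name}"] for ds in datasets
        )
        rows.append(row)
    table = pd.DataFrame(rows)
    return table, {k: round(v, 6) for k, v in coverage.items()}
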
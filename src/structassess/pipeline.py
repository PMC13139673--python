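"""End-to-end assessment runs: one config in, all report tables out.

A run takes a set of structure models, binding-site definitions, ligand
pose pairs and interaction jobs, and produces the model-comparison RMSD
matrix, per-site confidence reports, the redocking summary and the
key-residue fingerprint comparison, plus a provenance block (config hash,
seed, input digests) sufficient to reproduce the run. Stages are
independent: a failure in one is recorded and the others still run.
Outputs are deterministic — re-running the same config yields
byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from . import confidence as conf_mod
from . import interactions as int_mod
from . import io as io_mod
from . import ligand as lig_mod
from . import superpose as sup_mod

log = logging.getLogger("structassess")


@dataclass
class RunConfig:
    models: list[dict] = field(default_factory=list)       # {label, path, experimental?}
    sites: list[dict] = field(default_factory=list)        # {name, residues, neighbor_offsets?}
    pose_pairs: list[dict] = field(default_factory=list)   # {label, reference, pose, threshold?}
    interaction_jobs: list[dict] = field(default_factory=list)  # {model, ligand, site}
    output_dir: str = "assessment_out"
    seed: int = 0
    neighbor_offsets: tuple[int, ...] = conf_mod.DEFAULT_NEIGHBOR_OFFSETS
    chain_policy: str = "average_all"
    trimer_symmetry: bool = True
    precision: int = 2

    def __post_init__(self) -> None:
        labels = [m["label"] for m in self.models]
        if len(labels) != len(set(labels)):
            raise ValueError(f"model labels must be unique, got {labels}")
        for entry in self.models + [
            {"path": p["reference"]} for p in self.pose_pairs
        ] + [{"path": p["pose"]} for p in self.pose_pairs] + [
            {"path": j["ligand"]} for j in self.interaction_jobs
        ]:
            if not Path(entry["path"]).exists():
                raise FileNotFoundError(entry["path"])

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        run = raw.get("run", {})
        base = Path(path).parent

        def resolve(entry: dict, *keys: str) -> dict:
            out = dict(entry)
            for key in keys:
                if key in out:
                    out[key] = str((base / out[key]))
            return out

        return cls(
            models=[resolve(m, "path") for m in raw.get("models", [])],
            sites=list(raw.get("sites", [])),
            pose_pairs=[resolve(p, "reference", "pose") for p in raw.get("pose_pairs", [])],
            interaction_jobs=[resolve(j, "ligand") for j in raw.get("interaction_jobs", [])],
            output_dir=str(base / run.get("output_dir", "assessment_out")),
            seed=int(run.get("seed", 0)),
            neighbor_offsets=tuple(run.get("neighbor_offsets", conf_mod.DEFAULT_NEIGHBOR_OFFSETS)),
            chain_policy=run.get("chain_policy", "average_all"),
            trimer_symmetry=bool(run.get("trimer_symmetry", True)),
            precision=int(run.get("precision", 2)),
        )

    def site_definitions(self) -> list[conf_mod.SiteDefinition]:
        out = []
        for s in self.sites:
            out.append(
                conf_mod.SiteDefinition(
                    name=s["name"],
                    key_residues=[(int(n), c) for n, c in s["residues"]],
                    neighbor_offsets=tuple(s.get("neighbor_offsets", self.neighbor_offsets)),
                )
            )
        return out

    def canonical_hash(self) -> str:
        blob = json.dumps(
            {
                "models": self.models, "sites": self.sites,
                "pose_pairs": self.pose_pairs, "interaction_jobs": self.interaction_jobs,
                "neighbor_offsets": list(self.neighbor_offsets),
                "chain_policy": self.chain_policy, "seed": self.seed,
                "trimer_symmetry": self.trimer_symmetry, "precision": self.precision,
            },
            sort_keys=True,
        ).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class AssessmentReport:
    rmsd_matrix: "object | None" = None
    site_confidence: dict = field(default_factory=dict)   # (model, site) -> report
    redocking: dict = field(default_factory=dict)         # label -> SymRmsdResult
    fingerprints: dict = field(default_factory=dict)      # site -> comparison DataFrame
    errors: dict = field(default_factory=dict)            # stage -> message
    provenance: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.errors


def _digest(path: str) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_assessment(config: RunConfig) -> AssessmentReport:
    report = AssessmentReport()
    report.provenance = {
        "config_hash": config.canonical_hash(),
        "seed": config.seed,
        "inputs": {
            m["label"]: _digest(m["path"]) for m in config.models
        },
    }

    models = {}
    for entry in config.models:
        try:
            model = io_mod.read_structure(entry["path"])
            model.id = entry["label"]
            if entry.get("experimental"):
                model.metadata["experimental"] = True
            models[entry["label"]] = model
        except Exception as exc:  # noqa: BLE001 - stage isolation
            report.errors[f"read:{entry['label']}"] = str(exc)
    sites = config.site_definitions()

    # model comparison matrix
    if len(models) >= 2:
        try:
            report.rmsd_matrix = sup_mod.rmsd_matrix(
                list(models.values()), trimer_symmetry=config.trimer_symmetry
            )
        except Exception as exc:  # noqa: BLE001
            report.errors["rmsd_matrix"] = str(exc)

    # per-site confidence
    for label, model in models.items():
        if model.is_experimental:
            continue
        try:
            cmap = conf_mod.residue_confidence(model)
        except Exception as exc:  # noqa: BLE001
            report.errors[f"confidence:{label}"] = str(exc)
            continue
        for site in sites:
            try:
                report.site_confidence[(label, site.name)] = conf_mod.site_confidence(
                    cmap, model, site, chain_policy=config.chain_policy
                )
            except Exception as exc:  # noqa: BLE001
                report.errors[f"site_confidence:{label}:{site.name}"] = str(exc)

    # redocking validation
    for pair in config.pose_pairs:
        try:
            ref = io_mod.read_ligand(pair["reference"])
            pose = io_mod.read_ligand(pair["pose"])
            report.redocking[pair["label"]] = lig_mod.symmetry_rmsd(
                ref, pose, threshold=float(pair.get("threshold", lig_mod.REDOCK_THRESHOLD))
            )
        except Exception as exc:  # noqa: BLE001
            report.errors[f"redock:{pair['label']}"] = str(exc)

    # interaction fingerprints, compared across models per site
    by_site: dict[str, dict] = {}
    site_by_name = {s.name: s for s in sites}
    for job in config.interaction_jobs:
        try:
            model = models[job["model"]]
            ligand = io_mod.read_ligand(job["ligand"])
            site = site_by_name[job["site"]]
            records = int_mod.detect_interactions(model, ligand)
            by_site.setdefault(site.name, {})[job["model"]] = int_mod.fingerprint(records, site)
        except Exception as exc:  # noqa: BLE001
            report.errors[f"interactions:{job.get('model')}:{job.get('site')}"] = str(exc)
    for site_name, reports in by_site.items():
        try:
            report.fingerprints[site_name] = int_mod.compare_fingerprints(reports)
        except Exception as exc:  # noqa: BLE001
            report.errors[f"fingerprints:{site_name}"] = str(exc)
    return report


def write_report(report: AssessmentReport, config: RunConfig) -> Path:
    """Write TSV/JSON per table plus a Markdown summary; returns the dir."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    nd = config.precision

    if report.rmsd_matrix is not None:
        sup_mod.rmsd_matrix_tsv(report.rmsd_matrix, outdir / "rmsd_matrix.tsv")

    conf_json = {}
    for (label, site_name), rep in sorted(report.site_confidence.items()):
        rows = conf_mod.report_to_rows(rep, nd)
        with open(outdir / f"confidence_{label}_{site_name}.tsv", "w") as fh:
            fh.write("Residue\tpLDDT (mean)\n")
            for name, value in rows:
                fh.write(f"{name}\t{value}\n")
        conf_json[f"{label}/{site_name}"] = {
            "per_residue": dict(rep.rounded(nd).per_residue),
            "global_average": round(rep.global_average, nd),
            "n_chains_used": rep.n_chains_used,
            "missing": rep.missing,
        }
    (outdir / "confidence.json").write_text(json.dumps(conf_json, indent=2, ensure_ascii=False) + "\n")

    redock = {
        label: {
            "sym_rmsd": round(r.sym_rmsd, 3),
            "naive_rmsd": None if r.naive_rmsd is None else round(r.naive_rmsd, 3),
            "threshold": r.threshold,
            "classification": lig_mod.classify_redock(r),
        }
        for label, r in sorted(report.redocking.items())
    }
    (outdir / "redocking.json").write_text(json.dumps(redock, indent=2) + "\n")

    for site_name, table in sorted(report.fingerprints.items()):
        table.to_csv(outdir / f"fingerprints_{site_name}.tsv", sep="\t")

    (outdir / "provenance.json").write_text(
        json.dumps({**report.provenance, "errors": report.errors}, indent=2, sort_keys=True) + "\n"
    )

    lines = ["# Assessment summary", "", f"Config hash: {report.provenance['config_hash']}", ""]
    if report.rmsd_matrix is not None:
        lines += ["## Model comparison (Cα RMSD, Å)", "",
                  report.rmsd_matrix.round(3).to_string(), ""]
    for key, data in conf_json.items():
        lines += [f"## Site confidence — {key}", ""]
        lines += [f"- {name}: {value}" for name, value in data["per_residue"].items()]
        lines += [f"- Global average: {data['global_average']}", ""]
    if redock:
        lines += ["## Redocking validation", ""]
        lines += [
            f"- {label}: sym RMSD {d['sym_rmsd']} Å -> {d['classification']}"
            for label, d in redock.items()
        ]
        lines.append("")
    for site_name, table in sorted(report.fingerprints.items()):
        lines += [f"## Interaction fingerprints — {site_name}", "", table.to_string(), ""]
    if report.errors:
        lines += ["## Stage errors", ""] + [f"- {k}: {v}" for k, v in report.errors.items()]
    (outdir / "summary.md").write_text("\n".join(lines) + "\n")
    return outdir
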
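"""File formats: alignments (PHYLIP/FASTA), model/run configuration, TSV output.

Alignment reading and writing goes through Biopython; a locus is one file
(or one alignment block) and a multi-locus dataset is a list of loci.
Population membership of each sample is resolved from the model's sample
map, by default the ``<population>_<index>`` naming convention used by the
simulator.

The configuration file is flat ``key = value`` text with an embedded
adjacency-matrix block::

    populations = pop1 pop2
    samples     = 20 20
    matrix:
    0 0
    d 0

Matrix row ``i``, column ``j``: ``*`` migration from ``j`` into ``i``,
``d`` divergence (``i`` derived from ``j``), ``D`` both, ``0`` none.
Population indices are 1-based in files, 0-based in code.
"""

from __future__ import annotations

import io as _io
import math
from dataclasses import dataclass, field
from pathlib import Path

from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from popsplit.likelihood import MutationModel
from popsplit.mcmc import ChainConfig, PriorSpec
from popsplit.popmodel import ParameterSet, PopulationModel, parse_adjacency_matrix

__all__ = [
    "SequenceData",
    "RunConfig",
    "read_alignments",
    "write_alignment",
    "read_config",
    "write_summary_tsv",
    "write_samples_tsv",
    "write_histogram_tsv",
]


@dataclass
class SequenceData:
    """Per-locus alignments plus the population label of every sample."""

    loci: list  # list of dict name -> sequence
    pop_of: dict  # sample name -> population index

    @property
    def n_loci(self) -> int:
        return len(self.loci)


@dataclass
class RunConfig:
    """Everything a run needs: model, priors, chain settings, truth values."""

    model: PopulationModel
    priors: dict = field(default_factory=dict)
    chain: ChainConfig = field(default_factory=ChainConfig)
    mutation: MutationModel = field(default_factory=MutationModel)
    true_params: ParameterSet | None = None
    loci: int = 10
    sites: int = 1000
    div_mode: str = "per-lineage-hazard"


def _to_alignment(aln: dict) -> MultipleSeqAlignment:
    return MultipleSeqAlignment(
        [SeqRecord(Seq(s), id=name, description="") for name, s in aln.items()])


def write_alignment(aln: dict, path, fmt: str = "phylip") -> None:
    """Write one locus; ``fmt``: 'phylip' (interleaved), 'phylip-sequential'
    or 'fasta'."""
    path = Path(path)
    AlignIO.write(_to_alignment(aln), str(path), fmt)


def _read_one(path: Path, fmt: str | None) -> dict:
    text = path.read_text()
    if fmt == "fasta" or (fmt is None and text.lstrip().startswith(">")):
        recs = list(SeqIO.parse(_io.StringIO(text), "fasta"))
        if not recs:
            raise ValueError(f"{path}: no FASTA records")
        return {r.id: str(r.seq).upper() for r in recs}
    # PHYLIP: try relaxed, interleaved and sequential grammars
    last_err = None
    for candidate in ("phylip-relaxed", "phylip", "phylip-sequential"):
        try:
            rec = AlignIO.read(_io.StringIO(text), candidate)
            out = {r.id: str(r.seq).upper() for r in rec}
            if len(out) != len(rec):
                raise ValueError("duplicated tip names")
            return out
        except Exception as e:  # try the next grammar
            last_err = e
    raise ValueError(f"{path}: cannot parse as PHYLIP ({last_err})")


def read_alignments(paths, model: PopulationModel | None = None,
                    fmt: str | None = None,
                    sample_map: dict | None = None) -> SequenceData:
    """Read one alignment file per locus into a :class:`SequenceData`.

    Populations are resolved through ``sample_map`` (name -> population
    label or index) or, failing that, the ``<population>_<k>`` naming
    convention.  Unknown samples, duplicated names and unequal sequence
    lengths within a locus are reported as errors.
    """
    loci = []
    pop_of: dict = {}
    for p in map(Path, paths):
        aln = _read_one(p, fmt)
        lengths = {len(s) for s in aln.values()}
        if len(lengths) != 1:
            raise ValueError(f"{p}: sequences of unequal length {sorted(lengths)}")
        loci.append(aln)
        for name in aln:
            if name in pop_of:
                continue
            if sample_map and name in sample_map:
                lab = sample_map[name]
                pop_of[name] = (model.index(lab) if model is not None
                                and isinstance(lab, str) else int(lab))
            elif model is not None:
                stem = name.rsplit("_", 1)[0]
                try:
                    pop_of[name] = model.index(stem)
                except KeyError:
                    raise ValueError(
                        f"{p}: sample {name!r} matches no population") from None
    names0 = set(loci[0])
    for i, aln in enumerate(loci[1:], start=2):
        if set(aln) != names0:
            raise ValueError(f"locus {i} has a different sample set")
    return SequenceData(loci, pop_of)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def _parse_prior(tokens: list[str]) -> PriorSpec:
    kind = tokens[0].lower()
    if kind == "uniform":
        return PriorSpec("uniform", float(tokens[1]), float(tokens[2]))
    if kind == "exponential":
        return PriorSpec("exponential", float(tokens[1]), float(tokens[2]),
                         mean=float(tokens[3]))
    raise ValueError(f"unknown prior kind {kind!r}")


def read_config(path) -> RunConfig:
    """Parse the flat key=value configuration with a matrix block."""
    lines = [l.split("#", 1)[0].strip()
             for l in Path(path).read_text().splitlines()]
    lines = [l for l in lines if l]
    kv: dict[str, str] = {}
    matrix_at = None
    for i, line in enumerate(lines):
        if matrix_at is not None and i > matrix_at:
            continue  # matrix rows handled below
        if line.rstrip(":").strip() == "matrix":
            matrix_at = i
            continue
        if "=" in line:
            k, v = line.split("=", 1)
            kv[k.strip().lower()] = v.strip()
        elif matrix_at is None:
            raise ValueError(f"cannot parse config line: {line!r}")
    if "populations" not in kv:
        raise ValueError("config must declare 'populations'")
    labels = kv["populations"].split()
    n = len(labels)
    matrix_rows = lines[matrix_at + 1:matrix_at + 1 + n] if matrix_at is not None else []
    if len(matrix_rows) != n:
        raise ValueError("matrix block must have one row per population")
    # keys appearing after the matrix block
    for line in lines[(matrix_at + 1 + n) if matrix_at is not None else 0:]:
        if "=" in line:
            k, v = line.split("=", 1)
            kv.setdefault(k.strip().lower(), v.strip())
    mig, div = parse_adjacency_matrix(matrix_rows)
    samples = [int(x) for x in kv.get("samples", " ".join(["0"] * n)).split()]
    model = PopulationModel(labels, samples, mig, div)

    priors: dict[str, PriorSpec] = {}
    for k, v in kv.items():
        if k.endswith("_prior"):
            stem = k[:-6]
            priors[stem] = _parse_prior(v.split())
    chain = ChainConfig(
        length=int(kv.get("length", 20000)),
        burnin=int(kv.get("burnin", 5000)),
        thin=int(kv.get("thin", 10)),
        bins=int(kv.get("bins", 1500)),
        seed=int(kv.get("seed", 0)),
        genealogy_weight=float(kv.get("genealogy_weight", 0.6)),
    )
    freqs = tuple(float(x) for x in kv.get(
        "base_freqs", "0.25 0.25 0.25 0.25").split())
    mutation = MutationModel(freqs=freqs, kappa=float(kv.get("kappa", 1.5)))

    true_params = None
    if "true_theta" in kv:
        theta = tuple(float(x) for x in kv["true_theta"].split())
        mig_rates = {}
        if "true_mig" in kv:
            vals = [float(x) for x in kv["true_mig"].split()]
            for (e, val) in zip(sorted(mig), vals):
                mig_rates[e] = val
        div_mean, div_sd = {}, {}
        if "true_tau" in kv:
            taus = [float(x) for x in kv["true_tau"].split()]
            sds = [float(x) for x in kv.get("true_sigma", "").split()] or [
                t * 1e-4 for t in taus]
            for e, tm, sd in zip(sorted(div), taus, sds):
                div_mean[e] = tm
                div_sd[e] = sd
        true_params = ParameterSet(theta=theta, mig=mig_rates,
                                   div_mean=div_mean, div_sd=div_sd)
    return RunConfig(model=model, priors=priors, chain=chain,
                     mutation=mutation, true_params=true_params,
                     loci=int(kv.get("loci", 10)),
                     sites=int(kv.get("sites", 1000)),
                     div_mode=kv.get("div_mode", "per-lineage-hazard"))


def resolve_priors(cfg: RunConfig) -> dict:
    """Expand per-class priors (theta/mig/tau/sigma) to per-parameter names."""
    from popsplit.mcmc import _param_entries, default_priors

    out = default_priors(cfg.model)
    for name, kind, _ in _param_entries(cfg.model):
        stem = {"theta": "theta", "mig": "mig",
                "div_mean": "tau", "div_sd": "sigma"}[kind]
        if name.lower() in cfg.priors:
            out[name] = cfg.priors[name.lower()]
        elif stem in cfg.priors:
            out[name] = cfg.priors[stem]
    return out


# ---------------------------------------------------------------------------
# TSV output (every file embeds seed + config for reproducibility)
# ---------------------------------------------------------------------------

def _header_lines(seed: int, extra: dict | None = None) -> str:
    from popsplit import __version__
    items = {"popsplit_version": __version__, "seed": seed, **(extra or {})}
    return "".join(f"# {k} = {v}\n" for k, v in items.items())


def write_samples_tsv(path, result, extra: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(result.seed, extra))
        fh.write("iteration\t" + "\t".join(result.param_names) + "\tlog_posterior\n")
        for i, row in enumerate(result.samples):
            fh.write(str(i) + "\t" + "\t".join(f"{v:.10g}" for v in row)
                     + f"\t{result.log_posterior_trace[i]:.6f}\n")


def write_summary_tsv(path, result, extra: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(result.seed, extra))
        fh.write("parameter\tmode\tmean\tp2.5\tp97.5\tstd_width\tess\n")
        for name in result.param_names:
            s = result.summaries[name]
            fh.write(f"{name}\t{s.mode:.10g}\t{s.mean:.10g}\t{s.p2_5:.10g}\t"
                     f"{s.p97_5:.10g}\t{s.std_width:.6g}\t{s.ess:.1f}\n")


def write_histogram_tsv(path, result, extra: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(result.seed, extra))
        fh.write("parameter\tbin_mid\tdensity\n")
        for name in result.param_names:
            s = result.summaries[name]
            mids = 0.5 * (s.edges[:-1] + s.edges[1:]) if len(s.edges) > 1 else s.edges
            for m, d in zip(mids, s.hist):
                fh.write(f"{name}\t{m:.10g}\t{d:.10g}\n")
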
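"""The plain-text configuration dialect and its validation.

A configuration is line-oriented; ``#`` starts a comment. Units are fixed:
lengths in µm, times in s, diffusion coefficients in µm² s⁻¹. Statements:

``species <name>...``
    Declare one or more species.
``difc <species>[(state)] <D>``
    Default diffusion coefficient for a species (state optional, default
    ``surface``). A repeated key overwrites with a logged warning.
``surface_difc <surface> <species>[(state)] <D>``
    Per-surface exception to the default coefficient — the statement this
    dialect exists for. Used in addition to ``difc``, never instead of it.
``surface <name>`` followed by ``tri x1 y1 z1 x2 y2 z2 x3 y3 z3`` lines
    Declare a named surface and its triangular panels.
``reaction <name> <A> [+ <B>] -> <products|0> <rate>``
    Reaction channel; order inferred from the reactant side (``0`` for a
    zeroth-order source). Products are ``+``-separated or ``0`` for none.
``reversible <forward> <reverse> [pgem]``
    Mark ``reverse`` as the dissociation channel of the order-2 ``forward``
    reaction; products are placed an unbinding radius apart calibrated to the
    geminate-recombination probability ``pgem`` (default 0.2).
``mol <n> <species> surface=<name> random``
    Initial placement, uniform over the named surface.
``confine <species>``
    The species never crosses between surfaces: shared edges reflect it.
``time_start/time_stop/time_step <value>``, ``random_seed <int>``
``output_interval <steps>``, ``max_crossings <n>``
``output counts <file>``
``output trajectory <species|id> <file>``
"""

from __future__ import annotations

import logging
import shlex
from dataclasses import dataclass, field, replace
from pathlib import Path

from .diffusion import DEFAULT_STATE, DiffusionTable
from .engine import CountSeries, Simulation, TrajectoryRecord
from .geometry import MeshError, SurfaceMesh, build_mesh
from .reactions import ReactionDef

__all__ = ["Config", "ConfigError", "parse", "parse_file", "serialize", "validate",
           "build_simulation"]

log = logging.getLogger("surfdiff")


class ConfigError(ValueError):
    """Configuration problem, reported with the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        prefix = f"line {line}: " if line is not None else ""
        super().__init__(prefix + message)


@dataclass
class Config:
    """Parsed configuration, still symbolic (no mesh or tables built)."""

    species: tuple[str, ...] = ()
    difc: tuple[tuple[str, str, float], ...] = ()  # (species, state, D)
    surface_difc: tuple[tuple[str, str, str, float], ...] = ()  # (surface, sp, st, D)
    surfaces: tuple[tuple[str, tuple[tuple[float, ...], ...]], ...] = ()
    reactions: tuple[ReactionDef, ...] = ()
    reversible: tuple[tuple[str, str, float | None], ...] = ()
    placements: tuple[tuple[int, str, str], ...] = ()  # (n, species, surface)
    confined: tuple[str, ...] = ()
    time_start: float = 0.0
    time_stop: float | None = None
    time_step: float | None = None
    random_seed: int = 0
    output_interval: int = 1
    max_crossings: int = 1000
    outputs: tuple[tuple[str, ...], ...] = ()  # ("counts", path) | ("trajectory", sel, path)


def _parse_species_state(token: str) -> tuple[str, str]:
    if "(" in token:
        if not token.endswith(")"):
            raise ValueError(f"malformed species token {token!r}")
        name, state = token[:-1].split("(", 1)
        return name, state
    return token, DEFAULT_STATE


def _parse_reaction(args: list[str], lineno: int) -> ReactionDef:
    if len(args) < 4 or "->" not in args:
        raise ConfigError("reaction needs: name reactants -> products rate", lineno)
    name = args[0]
    arrow = args.index("->")
    lhs = [t for t in args[1:arrow] if t != "+"]
    rhs = [t for t in args[arrow + 1 : -1] if t != "+"]
    try:
        rate = float(args[-1])
    except ValueError:
        raise ConfigError(f"reaction {name}: bad rate {args[-1]!r}", lineno) from None
    reactants = [] if lhs == ["0"] else [_parse_species_state(t) for t in lhs]
    products = [] if rhs == ["0"] else [_parse_species_state(t) for t in rhs]
    order = len(reactants)
    if order > 2:
        raise ConfigError(f"reaction {name}: at most two reactants", lineno)
    try:
        return ReactionDef(name, order, reactants, products, rate)
    except ValueError as err:
        raise ConfigError(str(err), lineno) from None


def parse(text: str) -> Config:
    """Parse configuration text; errors carry 1-based line numbers."""
    species: list[str] = []
    difc: dict[tuple[str, str], float] = {}
    difc_lines: dict[tuple[str, str], int] = {}
    surface_difc: dict[tuple[str, str, str], float] = {}
    surfaces: dict[str, list[tuple[float, ...]]] = {}
    reactions: list[ReactionDef] = []
    reversible: list[tuple[str, str, float | None]] = []
    placements: list[tuple[int, str, str]] = []
    confined: list[str] = []
    outputs: list[tuple[str, ...]] = []
    scalars: dict[str, float | int] = {}
    current_surface: str | None = None
    deferred: list[tuple[int, str, tuple]] = []  # cross-reference checks

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        try:
            tokens = shlex.split(line)
        except ValueError as err:
            raise ConfigError(str(err), lineno) from None
        stmt, args = tokens[0], tokens[1:]

        if stmt == "species":
            if not args:
                raise ConfigError("species statement needs at least one name", lineno)
            for name in args:
                if name not in species:
                    species.append(name)
        elif stmt == "difc":
            if len(args) != 2:
                raise ConfigError("difc needs: species[(state)] value", lineno)
            sp, st = _parse_species_state(args[0])
            if sp not in species:
                raise ConfigError(f"difc references undeclared species {sp!r}", lineno)
            key = (sp, st)
            if key in difc:
                log.warning(
                    "line %d: difc for %s(%s) re-declared; last value wins",
                    lineno, sp, st,
                )
            difc[key] = _number(args[1], "difc value", lineno)
            difc_lines[key] = lineno
        elif stmt == "surface_difc":
            if len(args) != 3:
                raise ConfigError(
                    "surface_difc needs: surface species[(state)] value", lineno
                )
            sp, st = _parse_species_state(args[1])
            if sp not in species:
                raise ConfigError(
                    f"surface_difc references undeclared species {sp!r}", lineno
                )
            key3 = (args[0], sp, st)
            if key3 in surface_difc:
                log.warning(
                    "line %d: surface_difc for %s re-declared; last value wins",
                    lineno, key3,
                )
            surface_difc[key3] = _number(args[2], "surface_difc value", lineno)
            deferred.append((lineno, "surface", (args[0],)))
            deferred.append((lineno, "difc_default", ((sp, st),)))
        elif stmt == "surface":
            if len(args) != 1:
                raise ConfigError("surface needs exactly one name", lineno)
            current_surface = args[0]
            surfaces.setdefault(current_surface, [])
        elif stmt == "tri":
            if current_surface is None:
                raise ConfigError("tri outside of a surface block", lineno)
            if len(args) != 9:
                raise ConfigError("tri needs 9 coordinates", lineno)
            surfaces[current_surface].append(
                tuple(_number(a, "tri coordinate", lineno) for a in args)
            )
        elif stmt == "reaction":
            rxn = _parse_reaction(args, lineno)
            for sp, _ in rxn.reactants + rxn.products:
                if sp not in species:
                    raise ConfigError(
                        f"reaction {rxn.name} references undeclared species {sp!r}",
                        lineno,
                    )
            if any(r.name == rxn.name for r in reactions):
                raise ConfigError(f"duplicate reaction name {rxn.name!r}", lineno)
            reactions.append(rxn)
        elif stmt == "reversible":
            if len(args) not in (2, 3):
                raise ConfigError("reversible needs: forward reverse [pgem]", lineno)
            pg = _number(args[2], "pgem", lineno) if len(args) == 3 else None
            if pg is not None and not 0.0 <= pg < 1.0:
                raise ConfigError("pgem must lie in [0, 1)", lineno)
            reversible.append((args[0], args[1], pg))
            deferred.append((lineno, "reaction", (args[0],)))
            deferred.append((lineno, "reaction", (args[1],)))
        elif stmt == "mol":
            if (
                len(args) != 4
                or not args[2].startswith("surface=")
                or args[3] != "random"
            ):
                raise ConfigError(
                    "mol needs: n species surface=<name> random", lineno
                )
            n = int(_number(args[0], "molecule count", lineno))
            if n < 0:
                raise ConfigError("molecule count must be >= 0", lineno)
            if args[1] not in species:
                raise ConfigError(
                    f"mol references undeclared species {args[1]!r}", lineno
                )
            surf = args[2].split("=", 1)[1]
            placements.append((n, args[1], surf))
            deferred.append((lineno, "surface", (surf,)))
        elif stmt == "confine":
            if len(args) != 1:
                raise ConfigError("confine needs exactly one species", lineno)
            if args[0] not in species:
                raise ConfigError(
                    f"confine references undeclared species {args[0]!r}", lineno
                )
            if args[0] not in confined:
                confined.append(args[0])
        elif stmt in ("time_start", "time_stop", "time_step"):
            if len(args) != 1:
                raise ConfigError(f"{stmt} needs one value", lineno)
            scalars[stmt] = _number(args[0], stmt, lineno)
        elif stmt in ("random_seed", "output_interval", "max_crossings"):
            if len(args) != 1:
                raise ConfigError(f"{stmt} needs one value", lineno)
            scalars[stmt] = int(_number(args[0], stmt, lineno))
        elif stmt == "output":
            if len(args) == 2 and args[0] == "counts":
                outputs.append(("counts", args[1]))
            elif len(args) == 3 and args[0] == "trajectory":
                outputs.append(("trajectory", args[1], args[2]))
            else:
                raise ConfigError(
                    "output needs: counts <file> | trajectory <species|id> <file>",
                    lineno,
                )
        else:
            raise ConfigError(f"unknown statement {stmt!r}", lineno)

    reaction_names = {r.name for r in reactions}
    for lineno, kind, payload in deferred:
        if kind == "surface" and payload[0] not in surfaces:
            raise ConfigError(f"undeclared surface {payload[0]!r}", lineno)
        if kind == "difc_default" and payload[0] not in difc:
            sp, st = payload[0]
            raise ConfigError(
                f"surface_difc for {sp}({st}) has no difc default", lineno
            )
        if kind == "reaction" and payload[0] not in reaction_names:
            raise ConfigError(f"undeclared reaction {payload[0]!r}", lineno)

    # attach reversibility to the reaction definitions
    by_name = {r.name: r for r in reactions}
    for fwd, rev, pg in reversible:
        if by_name[fwd].order != 2:
            raise ConfigError(f"reversible forward {fwd!r} must be order 2")
        by_name[rev] = replace(
            by_name[rev], reversible_partner=fwd,
            pgem=pg if pg is not None else by_name[rev].pgem,
        )
    reactions = [by_name[r.name] for r in reactions]

    return Config(
        species=tuple(species),
        difc=tuple((sp, st, D) for (sp, st), D in difc.items()),
        surface_difc=tuple(
            (sf, sp, st, D) for (sf, sp, st), D in surface_difc.items()
        ),
        surfaces=tuple((name, tuple(tris)) for name, tris in surfaces.items()),
        reactions=tuple(reactions),
        reversible=tuple(reversible),
        placements=tuple(placements),
        confined=tuple(confined),
        time_start=float(scalars.get("time_start", 0.0)),
        time_stop=(
            float(scalars["time_stop"]) if "time_stop" in scalars else None
        ),
        time_step=(
            float(scalars["time_step"]) if "time_step" in scalars else None
        ),
        random_seed=int(scalars.get("random_seed", 0)),
        output_interval=int(scalars.get("output_interval", 1)),
        max_crossings=int(scalars.get("max_crossings", 1000)),
        outputs=tuple(outputs),
    )


def _number(token: str, what: str, lineno: int) -> float:
    try:
        return float(token)
    except ValueError:
        raise ConfigError(f"bad {what}: {token!r}", lineno) from None


def parse_file(path) -> Config:
    return parse(Path(path).read_text())


def _fmt_species(sp: str, st: str) -> str:
    return sp if st == DEFAULT_STATE else f"{sp}({st})"


def serialize(config: Config) -> str:
    """Canonical text form; ``parse(serialize(parse(t)))`` equals ``parse(t)``."""
    lines: list[str] = []
    if config.species:
        lines.append("species " + " ".join(config.species))
    for sp, st, D in config.difc:
        lines.append(f"difc {_fmt_species(sp, st)} {D!r}")
    for name, tris in config.surfaces:
        lines.append(f"surface {name}")
        for t in tris:
            lines.append("tri " + " ".join(repr(float(v)) for v in t))
    for sf, sp, st, D in config.surface_difc:
        lines.append(f"surface_difc {sf} {_fmt_species(sp, st)} {D!r}")
    for r in config.reactions:
        lhs = " + ".join(_fmt_species(*t) for t in r.reactants) or "0"
        rhs = " + ".join(_fmt_species(*t) for t in r.products) or "0"
        lines.append(f"reaction {r.name} {lhs} -> {rhs} {r.rate!r}")
    for fwd, rev, pg in config.reversible:
        lines.append(
            f"reversible {fwd} {rev}" + (f" {pg!r}" if pg is not None else "")
        )
    for sp in config.confined:
        lines.append(f"confine {sp}")
    for n, sp, surf in config.placements:
        lines.append(f"mol {n} {sp} surface={surf} random")
    lines.append(f"time_start {config.time_start!r}")
    if config.time_stop is not None:
        lines.append(f"time_stop {config.time_stop!r}")
    if config.time_step is not None:
        lines.append(f"time_step {config.time_step!r}")
    lines.append(f"random_seed {config.random_seed}")
    lines.append(f"output_interval {config.output_interval}")
    lines.append(f"max_crossings {config.max_crossings}")
    for out in config.outputs:
        lines.append("output " + " ".join(out))
    return "\n".join(lines) + "\n"


def validate(config: Config) -> Config:
    """Cross-reference checks plus a trial mesh/table build; returns the config."""
    if config.time_step is None or config.time_step <= 0:
        raise ConfigError("time_step must be declared and positive")
    if config.time_stop is None:
        raise ConfigError("time_stop must be declared")
    if config.time_stop < config.time_start:
        raise ConfigError("time_stop must be >= time_start")
    if not config.surfaces or all(not tris for _, tris in config.surfaces):
        raise ConfigError("no surface panels declared")
    mesh = _build_mesh(config)
    table = _build_difc_table(config)
    for n, sp, surf in config.placements:
        table.lookup(sp, DEFAULT_STATE, surf)
    for kind, *rest in config.outputs:
        if kind == "trajectory" and not rest[0].isdigit():
            if rest[0] not in config.species:
                raise ConfigError(
                    f"trajectory output references undeclared species {rest[0]!r}"
                )
    _ = mesh
    return config


def _build_mesh(config: Config) -> SurfaceMesh:
    tris: list = []
    labels: list[str] = []
    for name, panel_list in config.surfaces:
        for t in panel_list:
            tris.append([t[0:3], t[3:6], t[6:9]])
            labels.append(name)
    try:
        return build_mesh(tris, labels)
    except MeshError as err:
        raise ConfigError(str(err)) from None


def _build_difc_table(config: Config) -> DiffusionTable:
    table = DiffusionTable()
    for sp, st, D in config.difc:
        table.set_default(sp, D, state=st)
    for sp in config.species:  # species without difc default to immobile
        if not any(s == sp for s, _, _ in config.difc):
            table.set_default(sp, 0.0)
    for sf, sp, st, D in config.surface_difc:
        table.set_override(sf, sp, D, state=st)
    return table


def build_simulation(
    config: Config, seed: int | None = None
) -> tuple[Simulation, list[tuple]]:
    """Construct the ready-to-run simulation and its observers.

    Returns ``(simulation, outputs)`` where outputs pairs each observer with
    the relative path it should be written to: ``(kind, observer, path)``.
    """
    config = validate(config)
    mesh = _build_mesh(config)
    table = _build_difc_table(config)
    sim = Simulation(
        mesh,
        table,
        list(config.reactions),
        dt=config.time_step,
        seed=config.random_seed if seed is None else seed,
        time_start=config.time_start,
        time_stop=config.time_stop,
        confined_species=set(config.confined),
        output_interval=config.output_interval,
        max_crossings=config.max_crossings,
    )
    for n, sp, surf in config.placements:
        sim.place(n, sp, surf)
    outputs: list[tuple] = []
    for out in config.outputs:
        if out[0] == "counts":
            obs = CountSeries()
            sim.add_observer(obs)
            outputs.append(("counts", obs, out[1]))
        else:
            sel = out[1]
            if sel.isdigit():
                obs = TrajectoryRecord(molecule_id=int(sel))
            else:
                obs = TrajectoryRecord(species=sel)
            sim.add_observer(obs)
            outputs.append(("trajectory", obs, out[2]))
    return sim, outputs
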
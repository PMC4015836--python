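"""Filter-descriptor mini-language, plug-in registry, chain execution.

Filters are described by shell-friendly strings of the form::

    name:key=value,key=value

and joined into pipelines with ``+``, e.g. ``median:w=2+mlv:w=2``.  Values
that contain ``,``, ``:`` or ``+`` (nested chains, shape descriptors) are
bracketed: ``byslice:filter=[binarize:min=10,max=20]``.  This dialect is
this package's own; it is documented, round-trippable and makes no claim
of byte compatibility with any other tool.

Plug-ins live in a :class:`Registry` per kind (2D filters, 3D filters,
streaming filters, shapes).  A registry entry declares its parameters with
type, default and help text; creation from a descriptor validates every
parameter up front and yields an immutable :class:`Filter` whose
parameters can never be changed afterwards.  ``describe_registry`` renders
the same declarations as machine-readable JSON-compatible help.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Any, Callable, Sequence

from .core import Image, StoragePool
from .errors import (
    ChainExecutionError,
    DescriptorParseError,
    ParameterError,
    UnknownPluginError,
)

__all__ = [
    "FilterDescriptor",
    "parse_descriptor",
    "parse_chain",
    "format_descriptor",
    "format_chain",
    "ParamDecl",
    "Registry",
    "Filter",
    "PipelineContext",
    "create_filter",
    "run_chain",
    "describe_registry",
    "registry_help_text",
]

_NAME_RE = re.compile(r"[a-z0-9][a-z0-9_-]*\Z")
# characters that force bracketing of a parameter value
_SPECIAL = set(",:+[]")


@dataclass(frozen=True)
class FilterDescriptor:
    """Parsed form of one ``name:key=val,...`` descriptor.

    Parameter values are kept as raw strings; typing happens against the
    plug-in's parameter declarations at creation time.
    """

    name: str
    params: tuple[tuple[str, str], ...] = ()

    @property
    def param_map(self) -> dict[str, str]:
        return dict(self.params)

    def __str__(self) -> str:
        return format_descriptor(self)


def _split_top_level(text: str, sep: str, base: int) -> list[tuple[int, str]]:
    """Split on ``sep`` at bracket depth 0, returning (offset, piece) pairs."""
    pieces: list[tuple[int, str]] = []
    depth = 0
    start = 0
    for i, ch in enumerate(text):
        if ch == "[":
            depth += 1
        elif ch == "]":
            depth -= 1
            if depth < 0:
                raise DescriptorParseError("unbalanced ']'", base + i)
        elif ch == sep and depth == 0:
            pieces.append((base + start, text[start:i]))
            start = i + 1
    if depth != 0:
        raise DescriptorParseError("unbalanced '['", base + len(text))
    pieces.append((base + start, text[start:]))
    return pieces


def parse_chain(text: str) -> list[FilterDescriptor]:
    """Parse a ``+``-joined pipeline of descriptors, order preserved."""
    if not text.strip():
        raise DescriptorParseError("empty filter chain", 0)
    out = []
    for off, piece in _split_top_level(text, "+", 0):
        if not piece.strip():
            raise DescriptorParseError("empty chain segment", off)
        out.append(_parse_descriptor_at(piece, off))
    return out


def parse_descriptor(text: str) -> FilterDescriptor:
    """Parse a single descriptor string."""
    return _parse_descriptor_at(text, 0)


def _parse_descriptor_at(text: str, base: int) -> FilterDescriptor:
    head = _split_top_level(text, ":", base)
    name = head[0][1].strip()
    if not name:
        raise DescriptorParseError("empty plugin name", base)
    if not _NAME_RE.match(name):
        raise DescriptorParseError(f"invalid plugin name {name!r}", base)
    if len(head) == 1:
        return FilterDescriptor(name)
    # re-join everything after the first top-level ':' — further ':' belong
    # to parameter values and must be bracketed there
    rest_off = head[1][0]
    rest = text[rest_off - base:]
    params: list[tuple[str, str]] = []
    seen: set[str] = set()
    for off, item in _split_top_level(rest, ",", rest_off):
        if "=" not in item:
            raise DescriptorParseError(f"expected key=value, got {item!r}", off)
        key, _, value = item.partition("=")
        key = key.strip()
        if not key or not _NAME_RE.match(key):
            raise DescriptorParseError(f"invalid parameter key {key!r}", off)
        if key in seen:
            raise DescriptorParseError(f"duplicate parameter key {key!r}", off)
        seen.add(key)
        value = value.strip()
        if value.startswith("["):
            depth = 0
            close = -1
            for j, ch in enumerate(value):
                if ch == "[":
                    depth += 1
                elif ch == "]":
                    depth -= 1
                    if depth == 0:
                        close = j
                        break
            if close != len(value) - 1:
                raise DescriptorParseError("unterminated bracketed value",
                                           off + len(item))
            value = value[1:-1]
        else:
            bad = _SPECIAL.intersection(value)
            if bad:
                raise DescriptorParseError(
                    f"character {sorted(bad)[0]!r} in unbracketed value; use [...]",
                    off)
        params.append((key, value))
    return FilterDescriptor(name, tuple(params))


def format_descriptor(d: FilterDescriptor) -> str:
    """Canonical string form; ``parse(format(d)) == d``."""
    if not d.params:
        return d.name
    parts = []
    for key, value in d.params:
        if value == "" or _SPECIAL.intersection(value):
            value = f"[{value}]"
        parts.append(f"{key}={value}")
    return f"{d.name}:{','.join(parts)}"


def format_chain(descs: Sequence[FilterDescriptor]) -> str:
    return "+".join(format_descriptor(d) for d in descs)


# ---------------------------------------------------------------------------
# registry

@dataclass(frozen=True)
class ParamDecl:
    """Declaration of one plug-in parameter: type, default, help.

    ``type`` is one of ``int``, ``float``, ``str``, ``enum``, ``chain``
    (a nested descriptor chain, passed through raw), ``shape`` (a
    neighborhood-shape descriptor, passed through raw).
    """

    key: str
    type: str = "str"
    default: Any = None
    help: str = ""
    choices: tuple[str, ...] | None = None
    min: float | None = None
    max: float | None = None
    required: bool = False

    def convert(self, raw: str) -> Any:
        if self.type == "int":
            try:
                val: Any = int(raw)
            except ValueError:
                raise ParameterError(
                    f"parameter {self.key!r}: {raw!r} is not an integer") from None
        elif self.type == "float":
            try:
                val = float(raw)
            except ValueError:
                raise ParameterError(
                    f"parameter {self.key!r}: {raw!r} is not a number") from None
        elif self.type == "enum":
            if self.choices is None or raw not in self.choices:
                raise ParameterError(
                    f"parameter {self.key!r}: {raw!r} not one of "
                    f"{', '.join(self.choices or ())}")
            val = raw
        else:  # str, chain, shape stay raw
            val = raw
        if self.min is not None and isinstance(val, (int, float)) and val < self.min:
            raise ParameterError(
                f"parameter {self.key!r}: {val} below minimum {self.min}")
        if self.max is not None and isinstance(val, (int, float)) and val > self.max:
            raise ParameterError(
                f"parameter {self.key!r}: {val} above maximum {self.max}")
        return val


class Filter:
    """An immutable image filter created from a descriptor.

    Wraps an ``Image -> Image`` function; parameters were validated and
    frozen at creation time.
    """

    __slots__ = ("descriptor", "_fn", "rank")

    def __init__(self, descriptor: FilterDescriptor, fn: Callable[[Image], Image],
                 rank: int | None = None):
        self.descriptor = descriptor
        self._fn = fn
        self.rank = rank  # 2, 3, or None for rank-agnostic

    def apply(self, image: Image) -> Image:
        if self.rank is not None and image.rank != self.rank:
            raise ParameterError(
                f"filter {self.descriptor.name!r} expects rank {self.rank}, "
                f"got rank {image.rank} image")
        return self._fn(image)

    __call__ = apply

    def __repr__(self) -> str:
        return f"Filter({format_descriptor(self.descriptor)!r})"


@dataclass
class PipelineContext:
    """Per-run context handed to plug-in factories (pool, image rank)."""

    pool: StoragePool = field(default_factory=StoragePool)
    rank: int | None = None


@dataclass(frozen=True)
class PluginDef:
    name: str
    factory: Callable[..., Any]
    params: tuple[ParamDecl, ...]
    help: str


class Registry:
    """Name -> factory table for one plug-in kind.

    ``kind`` is one of ``filter2d``, ``filter3d``, ``fifof``, ``shape``.
    Factories receive the validated, typed parameters as keyword arguments
    plus ``context`` and return the plug-in object (a :class:`Filter` for
    image filters).
    """

    def __init__(self, kind: str):
        self.kind = kind
        self._plugins: dict[str, PluginDef] = {}

    def add(self, name: str, factory, params: Sequence[ParamDecl] = (),
            help: str = "") -> None:
        if not _NAME_RE.match(name):
            raise ValueError(f"invalid plugin name {name!r}")
        if name in self._plugins:
            raise ValueError(f"plugin {name!r} already registered in {self.kind}")
        self._plugins[name] = PluginDef(name, factory, tuple(params), help)

    def register(self, name: str, params: Sequence[ParamDecl] = (), help: str = ""):
        """Decorator form of :meth:`add`."""
        def deco(factory):
            self.add(name, factory, params, help)
            return factory
        return deco

    def names(self) -> list[str]:
        return sorted(self._plugins)

    def get(self, name: str) -> PluginDef:
        try:
            return self._plugins[name]
        except KeyError:
            raise UnknownPluginError(
                f"unknown {self.kind} plugin {name!r}; registered: "
                f"{', '.join(self.names())}") from None

    def create(self, spec: "str | FilterDescriptor",
               context: PipelineContext | None = None):
        if isinstance(spec, str):
            spec = parse_descriptor(spec)
        plugin = self.get(spec.name)
        decls = {p.key: p for p in plugin.params}
        kwargs: dict[str, Any] = {}
        for key, raw in spec.params:
            if key not in decls:
                raise ParameterError(
                    f"plugin {spec.name!r} has no parameter {key!r}; "
                    f"declared: {', '.join(decls) or 'none'}")
            kwargs[key] = decls[key].convert(raw)
        for decl in plugin.params:
            if decl.key not in kwargs:
                if decl.required:
                    raise ParameterError(
                        f"plugin {spec.name!r}: required parameter "
                        f"{decl.key!r} missing")
                kwargs[decl.key] = decl.default
        obj = plugin.factory(context=context or PipelineContext(), **kwargs)
        if isinstance(obj, Filter):
            return obj
        if callable(obj) and not hasattr(obj, "push"):
            return Filter(spec, obj)
        return obj  # streaming filters manage their own protocol


def create_filter(registry: Registry, spec: "str | FilterDescriptor",
                  pool: StoragePool | None = None) -> Filter:
    """Create one immutable filter from a descriptor."""
    ctx = PipelineContext(pool=pool if pool is not None else StoragePool())
    return registry.create(spec, ctx)


def run_chain(image: Image, specs: Sequence["str | Filter"], registry: Registry,
              pool: StoragePool | None = None) -> Image:
    """Apply a pipeline left to right; the input image is never modified.

    ``specs`` may mix descriptor strings (each may itself be a ``+`` chain)
    and already-created :class:`Filter` objects.  The first failing step
    aborts with a :class:`ChainExecutionError` naming the step index and
    descriptor text.
    """
    ctx = PipelineContext(pool=pool if pool is not None else StoragePool(),
                          rank=image.rank)
    steps: list[tuple[str, Filter]] = []
    for spec in specs:
        if isinstance(spec, Filter):
            steps.append((format_descriptor(spec.descriptor), spec))
        else:
            for desc in parse_chain(spec):
                text = format_descriptor(desc)
                try:
                    steps.append((text, registry.create(desc, ctx)))
                except Exception as e:
                    raise ChainExecutionError(len(steps), text, e) from e
    current = image.copy()
    for i, (text, filt) in enumerate(steps):
        try:
            current = filt.apply(current)
        except Exception as e:
            raise ChainExecutionError(i, text, e) from e
    return current


# ---------------------------------------------------------------------------
# auto-documentation

def describe_registry(registry: Registry) -> dict:
    """Machine-readable help: one entry per registered plug-in."""
    plugins = []
    for name in registry.names():
        plugin = registry.get(name)
        plugins.append({
            "name": name,
            "help": plugin.help,
            "params": [
                {
                    "key": p.key,
                    "type": p.type,
                    "default": p.default,
                    "help": p.help,
                    **({"choices": list(p.choices)} if p.choices else {}),
                }
                for p in plugin.params
            ],
        })
    return {"kind": registry.kind, "plugins": plugins}


def registry_help_text(registry: Registry) -> str:
    """Human-readable rendering of :func:`describe_registry`."""
    lines = [f"Available {registry.kind} plugins:"]
    for entry in describe_registry(registry)["plugins"]:
        lines.append(f"  {entry['name']}: {entry['help']}")
        for p in entry["params"]:
            extra = f" one of {', '.join(p['choices'])}" if "choices" in p else ""
            lines.append(f"    {p['key']} ({p['type']}, default={p['default']})"
                         f"{extra} — {p['help']}")
    return "\n".join(lines)
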
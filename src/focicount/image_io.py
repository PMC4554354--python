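"""Image loading, channel-role assignment, inversion and batch enumeration.

Micrographs arrive either as one multi-page TIFF holding all fluorescence
channels, or as per-channel single-plane files (TIFF or PNG) that share a
filename stem and differ only in a channel token (default ``_c{index}``,
e.g. ``field01_c0.png`` / ``field01_c1.png``).  Channel *roles* — the
nuclear-stain channel used for ROI selection (``roi``), the first foci
channel (``foci1``) and an optional second foci channel (``foci2``) — are
bound at load time.  At most three roles exist; raw pixel values are never
altered by loading.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import imageio.v3 as iio
import tifffile

from .errors import ConfigurationError, FormatError, InputError

ROLES = ("roi", "foci1", "foci2")
_EXTENSIONS = {".tif", ".tiff", ".png"}


@dataclass(frozen=True)
class ChannelAssignment:
    """Declares where each channel role lives.

    ``mode`` is ``"multichannel_file"`` (roles are page/channel indices
    inside one file) or ``"per_channel_files"`` (roles are the integer in
    the channel token of sibling files).  ``invert`` flags light-background
    images that must be complemented to the bright-on-dark convention.
    """

    mode: str = "multichannel_file"
    roi_channel: int = 0
    foci1_channel: int = 1
    foci2_channel: Optional[int] = None
    invert: bool = False
    channel_token: str = "_c{index}"

    def __post_init__(self) -> None:
        if self.mode not in ("multichannel_file", "per_channel_files"):
            raise ConfigurationError(f"unknown input mode {self.mode!r}")
        indices = [self.roi_channel, self.foci1_channel]
        if self.foci2_channel is not None:
            indices.append(self.foci2_channel)
        if len(set(indices)) != len(indices):
            raise ConfigurationError(
                "roi/foci1/foci2 must resolve to distinct channels, got "
                f"{indices}"
            )
        if "{index}" not in self.channel_token:
            raise ConfigurationError(
                "channel_token must contain the placeholder '{index}'"
            )

    @property
    def roles(self) -> dict:
        out = {"roi": self.roi_channel, "foci1": self.foci1_channel}
        if self.foci2_channel is not None:
            out["foci2"] = self.foci2_channel
        return out


@dataclass
class MultiChannelImage:
    """An ordered stack of same-shape 2-D grayscale rasters with the
    role → channel-index map resolved."""

    channels: list
    bit_depth: int
    source_path: str
    channel_roles: dict

    def __post_init__(self) -> None:
        shapes = {c.shape for c in self.channels}
        if len(shapes) != 1:
            raise FormatError(
                f"{self.source_path}: channel dimensions differ: {sorted(shapes)}"
            )
        if self.bit_depth not in (8, 16):
            raise FormatError(f"unsupported bit depth {self.bit_depth}")
        for role, idx in self.channel_roles.items():
            if role not in ROLES:
                raise ConfigurationError(f"unknown channel role {role!r}")
            if not (0 <= idx < len(self.channels)):
                raise ConfigurationError(
                    f"{self.source_path}: role {role!r} points at channel "
                    f"{idx}, but only {len(self.channels)} channel(s) exist"
                )
        if "roi" not in self.channel_roles or "foci1" not in self.channel_roles:
            raise ConfigurationError("roles 'roi' and 'foci1' must be assigned")
        if len(self.channel_roles) > 3:
            raise ConfigurationError("at most 3 channel roles are supported")

    @property
    def shape(self) -> tuple:
        return self.channels[0].shape

    def channel(self, role: str) -> np.ndarray:
        return self.channels[self.channel_roles[role]]


def _decode_planes(path: Path) -> list:
    """Decode a file into a list of single-plane unsigned-integer rasters."""
    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff"):
            arr = tifffile.imread(str(path))
        elif suffix == ".png":
            arr = iio.imread(str(path))
        else:
            raise FormatError(
                f"{path}: unsupported format {suffix!r} (TIFF/PNG only)")
    except FormatError:
        raise
    except Exception as exc:  # undecodable byte stream
        raise FormatError(f"{path}: cannot decode: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 2:
        planes = [arr]
    elif arr.ndim == 3:
        # Distinguish a channel/page stack from an RGB(A) raster: color
        # images carry 3 or 4 samples in the *last* axis.
        if arr.shape[-1] in (3, 4) and arr.shape[-1] < min(arr.shape[:2]):
            raise FormatError(
                f"{path}: color (RGB/RGBA) input is not analyzable; split it "
                "into single-channel grayscale files first"
            )
        planes = [arr[i] for i in range(arr.shape[0])]
    else:
        raise FormatError(f"{path}: expected a 2-D plane or a plane stack, "
                          f"got shape {arr.shape}")
    for p in planes:
        if p.dtype not in (np.uint8, np.uint16):
            raise FormatError(
                f"{path}: expected 8- or 16-bit unsigned grayscale, got {p.dtype}"
            )
    return planes


def _bit_depth(planes: Sequence[np.ndarray]) -> int:
    depth = 16 if any(p.dtype == np.uint16 for p in planes) else 8
    return depth


def _token_glob(token: str) -> str:
    return token.replace("{index}", "*")


def _sibling_path(path: Path, token: str, src_index: int, dst_index: int) -> Path:
    src = token.format(index=src_index)
    dst = token.format(index=dst_index)
    name = path.name
    if src not in name:
        raise InputError(f"{path}: filename does not contain channel token {src!r}")
    return path.with_name(name.replace(src, dst, 1))


def _find_channel_index(path: Path, token: str) -> Optional[int]:
    """Return the integer i such that token.format(index=i) occurs in the
    filename, or None."""
    prefix, suffix = token.split("{index}")
    name = path.stem + path.suffix
    start = 0
    while True:
        i = name.find(prefix, start)
        if i < 0:
            return None
        j = i + len(prefix)
        k = j
        while k < len(name) and name[k].isdigit():
            k += 1
        if k > j and name[k:].startswith(suffix):
            return int(name[j:k])
        start = i + 1


def load_image(path, assignment: ChannelAssignment) -> MultiChannelImage:
    """Load one logical multi-channel image and bind channel roles.

    In ``multichannel_file`` mode *path* is the file itself; in
    ``per_channel_files`` mode *path* may be any one of the sibling
    channel files (the others are resolved through the channel token).
    Pixel data is preserved bit-exactly; inversion is a separate,
    explicit step (:func:`invert_image`).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")

    if assignment.mode == "multichannel_file":
        planes = _decode_planes(path)
        channels = planes
        roles = dict(assignment.roles)
        source = str(path)
    else:
        own = _find_channel_index(path, assignment.channel_token)
        if own is None:
            raise InputError(
                f"{path}: cannot locate channel token "
                f"{assignment.channel_token!r} in filename"
            )
        needed = assignment.roles  # role -> token index
        channels = []
        index_map = {}
        for pos, (role, tok_idx) in enumerate(sorted(needed.items())):
            sib = _sibling_path(path, assignment.channel_token, own, tok_idx)
            if not sib.exists():
                raise InputError(
                    f"incomplete channel group for {path}: missing {sib.name}"
                )
            planes = _decode_planes(sib)
            if len(planes) != 1:
                raise FormatError(
                    f"{sib}: per-channel files must be single-plane"
                )
            channels.append(planes[0])
            index_map[role] = pos
        roles = index_map
        source = str(_sibling_path(path, assignment.channel_token, own,
                                   assignment.roles["roi"]))

    for role, idx in roles.items():
        if not (0 <= idx < len(channels)):
            raise ConfigurationError(
                f"{path}: role {role!r} requests channel {idx}, file has "
                f"{len(channels)} channel(s)"
            )
    return MultiChannelImage(
        channels=channels,
        bit_depth=_bit_depth(channels),
        source_path=source,
        channel_roles=roles,
    )


def invert_image(img: MultiChannelImage) -> MultiChannelImage:
    """Complement every pixel: v -> (2**bit_depth - 1) - v.

    Restores the bright-on-dark convention for light-background images.
    Applying it twice is the identity, bit-exactly.
    """
    top = np.uint32(2 ** img.bit_depth - 1)
    inverted = [(top - c.astype(np.uint32)).astype(c.dtype) for c in img.channels]
    return MultiChannelImage(
        channels=inverted,
        bit_depth=img.bit_depth,
        source_path=img.source_path,
        channel_roles=dict(img.channel_roles),
    )


@dataclass(frozen=True)
class ImageGroup:
    """One analyzable logical image inside a batch tree: a display name
    (relative path) plus the path load_image should receive."""

    name: str
    path: str


@dataclass
class BatchListing:
    groups: list = field(default_factory=list)
    skipped: list = field(default_factory=list)  # (name, reason)


def list_batch_inputs(root, assignment: ChannelAssignment) -> BatchListing:
    """Recursively enumerate analyzable images under *root*.

    Order is deterministic (lexicographic on the POSIX relative path).
    In per-channel mode, groups missing any required channel file are
    reported in ``skipped`` rather than analyzed silently.
    """
    root = Path(root)
    if not root.is_dir():
        raise InputError(f"not a directory: {root}")

    files = sorted(
        (p for p in root.rglob("*")
         if p.is_file() and p.suffix.lower() in _EXTENSIONS),
        key=lambda p: p.relative_to(root).as_posix(),
    )

    listing = BatchListing()
    if assignment.mode == "multichannel_file":
        for p in files:
            listing.groups.append(
                ImageGroup(name=p.relative_to(root).as_posix(), path=str(p)))
        return listing

    # per-channel mode: group by (directory, stem with token removed)
    needed = sorted(assignment.roles.values())
    seen_groups: dict = {}
    for p in files:
        idx = _find_channel_index(p, assignment.channel_token)
        if idx is None:
            listing.skipped.append(
                (p.relative_to(root).as_posix(), "no channel token in filename"))
            continue
        key = p.with_name(
            p.name.replace(assignment.channel_token.format(index=idx), "\x00", 1))
        seen_groups.setdefault(key, {})[idx] = p
    for key in sorted(seen_groups, key=lambda p: p.relative_to(root).as_posix()):
        members = seen_groups[key]
        missing = [i for i in needed if i not in members]
        display = key.relative_to(root).as_posix().replace("\x00", "")
        if missing:
            listing.skipped.append(
                (display, f"missing channel file(s) for index {missing}"))
        else:
            anchor = members[needed[0]]
            listing.groups.append(ImageGroup(name=display, path=str(anchor)))
    return listing


def save_raster(path, raster: np.ndarray) -> None:
    """Write one grayscale plane as TIFF or PNG (dtype preserved)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(str(path), raster)
    elif suffix == ".png":
        iio.imwrite(str(path), raster)
    else:
        raise FormatError(f"{path}: unsupported output format {suffix!r}")


def save_multichannel_tiff(path, img: MultiChannelImage) -> None:
    """Write all channels of *img* as one multi-page TIFF."""
    tifffile.imwrite(str(path), np.stack(img.channels),
                     photometric="minisblack")
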
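"""Minimal uncompressed AVI (RIFF) reader and writer for grayscale video.

High-speed cameras commonly deliver uncompressed AVI; this module writes
8-bit palettized DIB frames (the compact grayscale representation) and reads
both 8-bit palettized and 24-bit BI_RGB frames, converting color to
luminance with ITU-R BT.601 weights.  Only single-video-stream files with
uncompressed frames ('00db'/'00dc' chunks, biCompression = 0) are supported.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

_AVIF_HASINDEX = 0x00000010


def _chunk(fourcc: bytes, payload: bytes) -> bytes:
    data = payload if len(payload) % 2 == 0 else payload + b"\x00"
    return fourcc + struct.pack("<I", len(payload)) + data


def _list_chunk(listtype: bytes, payload: bytes) -> bytes:
    return _chunk(b"LIST", listtype + payload)


def write_avi(path: str | Path, frames: np.ndarray, fps: float) -> None:
    """Write a (n, h, w) uint8 stack as an uncompressed 8-bit grayscale AVI."""
    frames = np.asarray(frames)
    if frames.ndim != 3 or frames.dtype != np.uint8:
        raise ValueError("expected a (n_frames, h, w) uint8 stack")
    n, h, w = frames.shape
    row_bytes = (w + 3) & ~3  # DIB rows padded to 4 bytes
    frame_bytes = row_bytes * h

    avih = struct.pack("<14I", int(round(1e6 / fps)), frame_bytes * int(fps),
                       0, _AVIF_HASINDEX, n, 0, 1, frame_bytes, w, h,
                       0, 0, 0, 0)
    strh = (b"vids" + b"DIB " +
            struct.pack("<IHHIIIIIIIi4H", 0, 0, 0, 0, 1, int(round(fps)),
                        0, n, frame_bytes, 0, 0, 0, 0, w, h))
    # BITMAPINFOHEADER + 256-entry gray palette
    bmih = struct.pack("<IiiHHIIiiII", 40, w, h, 1, 8, 0, frame_bytes,
                       0, 0, 256, 0)
    palette = bytes(v for i in range(256) for v in (i, i, i, 0))
    strf = bmih + palette

    strl = _list_chunk(b"strl", _chunk(b"strh", strh) + _chunk(b"strf", strf))
    hdrl = _list_chunk(b"hdrl", _chunk(b"avih", avih) + strl)

    movi_payload = b"movi"
    index_entries = []
    for k in range(n):
        offset = len(movi_payload)  # offset of the chunk fourcc within movi
        rows = frames[k][::-1]  # DIB stores rows bottom-up
        if row_bytes != w:
            padded = np.zeros((h, row_bytes), dtype=np.uint8)
            padded[:, :w] = rows
            data = padded.tobytes()
        else:
            data = rows.tobytes()
        movi_payload += _chunk(b"00db", data)
        index_entries.append((offset, len(data)))
    movi = _chunk(b"LIST", movi_payload)

    idx1 = b"".join(struct.pack("<4sIII", b"00db", 0x10, off, size)
                    for off, size in index_entries)
    body = b"AVI " + hdrl + movi + _chunk(b"idx1", idx1)
    with open(path, "wb") as fh:
        fh.write(b"RIFF" + struct.pack("<I", len(body)) + body)


def _iter_chunks(data: bytes, start: int, end: int):
    pos = start
    while pos + 8 <= end:
        fourcc = data[pos:pos + 4]
        (size,) = struct.unpack("<I", data[pos + 4:pos + 8])
        yield fourcc, pos + 8, size
        pos += 8 + size + (size & 1)


def read_avi(path: str | Path) -> tuple[np.ndarray, float]:
    """Read an uncompressed AVI into a (n, h, w) uint8 grayscale stack.

    Returns ``(frames, fps)``.  24-bit frames are converted to luminance
    (ITU-R BT.601); 8-bit frames are mapped through their palette.
    """
    data = Path(path).read_bytes()
    if data[:4] != b"RIFF" or data[8:12] != b"AVI ":
        raise ValueError(f"{path}: not an AVI file")

    width = height = bitcount = None
    palette = None
    rate = scale = None
    frame_chunks: list[bytes] = []

    def walk(start: int, end: int) -> None:
        nonlocal width, height, bitcount, palette, rate, scale
        for fourcc, payload_at, size in _iter_chunks(data, start, end):
            payload_end = payload_at + size
            if fourcc == b"LIST":
                walk(payload_at + 4, payload_end)
            elif fourcc == b"strh" and size >= 48:
                body = data[payload_at:payload_end]
                if body[:4] == b"vids":
                    scale, rate = struct.unpack("<II", body[20:28])
            elif fourcc == b"strf" and width is None and size >= 40:
                body = data[payload_at:payload_end]
                (_, width, height, _, bitcount, compression) = struct.unpack(
                    "<IiiHHI", body[:20])
                if compression != 0:
                    raise ValueError("only uncompressed (BI_RGB) AVI "
                                     "is supported")
                if bitcount == 8:
                    pal = body[40:40 + 256 * 4]
                    palette = np.frombuffer(pal, dtype=np.uint8)
                    palette = palette.reshape(-1, 4)[:, :3]  # BGR
            elif fourcc in (b"00db", b"00dc") and size > 0:
                frame_chunks.append(data[payload_at:payload_end])

    walk(12, len(data))
    if width is None or not frame_chunks:
        raise ValueError(f"{path}: no uncompressed video frames found")
    h, w = abs(height), width
    bottom_up = height > 0
    frames = np.empty((len(frame_chunks), h, w), dtype=np.uint8)
    if bitcount == 8:
        row_bytes = (w + 3) & ~3
        lut = None
        if palette is not None:
            bgr = palette.astype(np.float64)
            lut = np.clip(np.rint(0.114 * bgr[:, 0] + 0.587 * bgr[:, 1]
                                  + 0.299 * bgr[:, 2]), 0, 255).astype(np.uint8)
        for k, raw in enumerate(frame_chunks):
            img = np.frombuffer(raw[:row_bytes * h],
                                dtype=np.uint8).reshape(h, row_bytes)[:, :w]
            if bottom_up:
                img = img[::-1]
            frames[k] = lut[img] if lut is not None else img
    elif bitcount == 24:
        row_bytes = (w * 3 + 3) & ~3
        for k, raw in enumerate(frame_chunks):
            img = np.frombuffer(raw[:row_bytes * h],
                                dtype=np.uint8).reshape(h, row_bytes)
            img = img[:, :w * 3].reshape(h, w, 3).astype(np.float64)  # BGR
            if bottom_up:
                img = img[::-1]
            lum = 0.114 * img[..., 0] + 0.587 * img[..., 1] + 0.299 * img[..., 2]
            frames[k] = np.clip(np.rint(lum), 0, 255).astype(np.uint8)
    else:
        raise ValueError(f"unsupported bit depth {bitcount}")
    fps = rate / scale if rate and scale else 0.0
    return frames, fps
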
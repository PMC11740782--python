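"""Core data containers: labelled ultrasound image records and cohort manifests.

Images travel in memory as 8-bit grayscale arrays; on disk a cohort is a
directory of PNG files plus a CSV manifest with columns
``path,patient_id,class,domain,provenance``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

CLASSES = ("normal", "benign", "malignant")
DOMAINS = ("standard", "pocus", "translated")

MANIFEST_COLUMNS = ["path", "patient_id", "class", "domain", "provenance"]


@dataclass
class ImageRecord:
    """One grayscale image with its label, acquisition domain and patient id."""

    pixels: np.ndarray  # 2-D uint8
    class_label: str
    domain: str
    patient_id: str
    provenance: str = "synthetic"

    def __post_init__(self):
        if self.class_label not in CLASSES:
            raise ValueError(f"unknown class label {self.class_label!r}; expected one of {CLASSES}")
        if self.domain not in DOMAINS:
            raise ValueError(f"unknown domain {self.domain!r}; expected one of {DOMAINS}")
        self.pixels = np.asarray(self.pixels)

    def content_hash(self) -> str:
        h = hashlib.sha1()
        h.update(np.ascontiguousarray(self.pixels).tobytes())
        h.update(str(self.pixels.shape).encode())
        return h.hexdigest()

    def with_pixels(self, pixels: np.ndarray, provenance: str | None = None) -> "ImageRecord":
        return replace(self, pixels=pixels,
                       provenance=self.provenance if provenance is None else provenance)


@dataclass
class CohortManifest:
    """An ordered collection of image records, optionally with a patient split."""

    records: list[ImageRecord] = field(default_factory=list)
    split: dict[str, str] | None = None  # patient_id -> {"train", "test"}

    def __post_init__(self):
        if self.split is not None:
            bad = {p: s for p, s in self.split.items() if s not in ("train", "test")}
            if bad:
                raise ValueError(f"split values must be 'train' or 'test': {bad}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def patient_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.patient_id, None)
        return list(seen)

    def subset(self, which: str) -> "CohortManifest":
        """Records whose patient falls in the given split ('train' or 'test')."""
        if self.split is None:
            raise ValueError("manifest has no split")
        recs = [r for r in self.records if self.split.get(r.patient_id) == which]
        return CohortManifest(recs, split=None)

    def filter(self, *, class_label=None, domain=None) -> "CohortManifest":
        recs = [
            r for r in self.records
            if (class_label is None or r.class_label == class_label)
            and (domain is None or r.domain == domain)
        ]
        return CohortManifest(recs, split=self.split)

    def merged_with(self, *others: "CohortManifest") -> "CohortManifest":
        recs = list(self.records)
        for o in others:
            recs.extend(o.records)
        return CohortManifest(recs)

    # -- disk round trip -----------------------------------------------------

    def save(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        img_dir = out_dir / "images"
        img_dir.mkdir(parents=True, exist_ok=True)
        rows = []
        for i, r in enumerate(self.records):
            name = f"{i:05d}_{r.patient_id}_{r.class_label}.png"
            Image.fromarray(r.pixels.astype(np.uint8), mode="L").save(img_dir / name)
            rows.append({"path": f"images/{name}", "patient_id": r.patient_id,
                         "class": r.class_label, "domain": r.domain,
                         "provenance": r.provenance})
        manifest_path = out_dir / "manifest.csv"
        pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest_path, index=False)
        if self.split is not None:
            pd.DataFrame(sorted(self.split.items()), columns=["patient_id", "split"]).to_csv(
                out_dir / "split.csv", index=False)
        return manifest_path

    @classmethod
    def load(cls, manifest_path: str | Path) -> "CohortManifest":
        manifest_path = Path(manifest_path)
        base = manifest_path.parent
        df = pd.read_csv(manifest_path, dtype=str)
        records = []
        for _, row in df.iterrows():
            pixels = np.asarray(Image.open(base / row["path"]).convert("L"))
            records.append(ImageRecord(pixels, row["class"], row["domain"],
                                       str(row["patient_id"]), row["provenance"]))
        split = None
        split_path = base / "split.csv"
        if split_path.exists():
            sdf = pd.read_csv(split_path, dtype=str)
            split = dict(zip(sdf["patient_id"], sdf["split"]))
        return cls(records, split=split)


def pixel_stack(manifest: CohortManifest, scale: bool = True) -> np.ndarray:
    """Stack a cohort into an (N, H, W) float array, optionally scaled to [0, 1]."""
    arr = np.stack([r.pixels.astype(np.float64) for r in manifest.records])
    return arr / 255.0 if scale else arr
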
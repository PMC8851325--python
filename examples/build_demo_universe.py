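"""Generate a three-university fixture universe for the README walkthrough.

Usage:  python examples/build_demo_universe.py OUT_DIR [SEED]

Writes one synthetic SHC site per university plus sites.json, the
university -> manifest map consumed by `shcqual --backend fixture`.
"""

import json
import sys
from pathlib import Path

from shcqual import TopicSpec, generate_site, random_site


def main() -> None:
    out = Path(sys.argv[1] if len(sys.argv) > 1 else "demo-universe")
    seed = int(sys.argv[2]) if len(sys.argv) > 2 else 1
    topic = TopicSpec(
        "LARC",
        ["IUD", "intrauterine device", "contraceptive implant",
         "contraceptive shot", "Depo Provera"],
    )
    universities = {
        "Alpha State University": ("shc.alpha-state.edu", 0.3),
        "Beta Polytechnic University": ("health.beta-poly.edu", 0.15),
        "Gamma College": ("wellness.gamma.edu", 0.0),  # no LARC content
    }
    mapping = {}
    for i, (name, (domain, fraction)) in enumerate(universities.items()):
        spec = random_site(
            seed=seed + i, n_pages=15, link_prob=0.2, topic=topic,
            keyword_page_fraction=fraction, domain=domain,
        )
        slug = domain.replace(".", "-")
        generate_site(spec, out / slug)
        mapping[name] = f"{slug}/manifest.json"
    (out / "sites.json").write_text(json.dumps(mapping, indent=2) + "\n")
    print(f"wrote {len(mapping)} fixture sites under {out}/")


if __name__ == "__main__":
    main()
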
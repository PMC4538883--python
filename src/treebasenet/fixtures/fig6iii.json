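{
 "format": "treebase-net-v1",
 "name": "fig6iii",
 "comment": "Acyclic, three leaves, no strong temporal ordering relative to any support tree (same crossing-linking-arc core as fig6ii).",
 "vertices": [
  {
   "id": "a",
   "label": "a"
  },
  {
   "id": "b",
   "label": "b"
  },
  {
   "id": "c",
   "label": "c"
  },
  {
   "id": "m"
  },
  {
   "id": "rho"
  },
  {
   "id": "s"
  },
  {
   "id": "x1"
  },
  {
   "id": "x2"
  },
  {
   "id": "y1"
  },
  {
   "id": "y2"
  }
 ],
 "arcs": [
  {
   "id": "e00",
   "source": "rho",
   "target": "s"
  },
  {
   "id": "e01",
   "source": "s",
   "target": "c"
  },
  {
   "id": "e02",
   "source": "s",
   "target": "m"
  },
  {
   "id": "e03",
   "source": "m",
   "target": "x1"
  },
  {
   "id": "e04",
   "source": "m",
   "target": "y1"
  },
  {
   "id": "e05",
   "source": "x1",
   "target": "x2"
  },
  {
   "id": "e06",
   "source": "x1",
   "target": "y2"
  },
  {
   "id": "e07",
   "source": "y1",
   "target": "y2"
  },
  {
   "id": "e08",
   "source": "y1",
   "target": "x2"
  },
  {
   "id": "e09",
   "source": "x2",
   "target": "a"
  },
  {
   "id": "e10",
   "source": "y2",
   "target": "b"
  }
 ]
}
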
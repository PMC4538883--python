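{
 "format": "treebase-net-v1",
 "name": "double_diamond",
 "comment": "Tree-based but not tree-sibling: both reticulations h1, h2 share both parents, so neither has an in-degree-1 sibling.",
 "vertices": [
  {
   "id": "h1"
  },
  {
   "id": "h2"
  },
  {
   "id": "p1"
  },
  {
   "id": "p2"
  },
  {
   "id": "rho"
  },
  {
   "id": "x",
   "label": "x"
  },
  {
   "id": "y",
   "label": "y"
  }
 ],
 "arcs": [
  {
   "id": "e00",
   "source": "rho",
   "target": "p1"
  },
  {
   "id": "e01",
   "source": "rho",
   "target": "p2"
  },
  {
   "id": "e02",
   "source": "p1",
   "target": "h1"
  },
  {
   "id": "e03",
   "source": "p1",
   "target": "h2"
  },
  {
   "id": "e04",
   "source": "p2",
   "target": "h1"
  },
  {
   "id": "e05",
   "source": "p2",
   "target": "h2"
  },
  {
   "id": "e06",
   "source": "h1",
   "target": "x"
  },
  {
   "id": "e07",
   "source": "h2",
   "target": "y"
  }
 ]
}
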
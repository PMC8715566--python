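# ICF category registry seed (partial by design).
# Columns: code	title	kind	parent
# Covers the nine Activities & Participation chapters, the five
# Environmental Factors chapters, one example block, and all categories
# used by the built-in case-study fixtures.
code	title	kind	parent
d1	Learning and applying knowledge	chapter
d2	General tasks and demands	chapter
d3	Communication	chapter
d4	Mobility	chapter
d5	Self-care	chapter
d6	Domestic life	chapter
d7	Interpersonal interactions and relationships	chapter
d8	Major life areas	chapter
d9	Community, social and civic life	chapter
d330-d349	Communicating - producing	block	d3
d410	Changing basic body positions	category	d4
d415	Maintaining a body position	category	d4
d4153	Maintaining a sitting position	category	d415
d4154	Maintaining a standing position	category	d415
d420	Transferring oneself	category	d4
d4200	Transferring oneself while sitting	category	d420
d430	Lifting and carrying objects	category	d4
d4300	Lifting	category	d430
d440	Fine hand use	category	d4
d445	Hand and arm use	category	d4
d465	Moving around using equipment	category	d4
d720	Complex interpersonal interactions	category	d7
d7202	Regulating behaviours within interactions	category	d720
d850	Remunerative employment	category	d8
e1	Products and technology	chapter
e2	Natural environment and human-made changes to environment	chapter
e3	Support and relationships	chapter
e4	Attitudes	chapter
e5	Services, systems and policies	chapter
e110	Products or substances for personal consumption	category	e1
e1101	Drugs	category	e110
e115	Products and technology for personal use in daily living	category	e1
e1151	Assistive products and technology for personal mobility	category	e115
e155	Design, construction and building products and technology of buildings for private use	category	e1
e580	Health services, systems and policies	category	e5
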
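term	category
Profound mental retardation (PMR)	cognitive
Cognitive impairment	cognitive
Speech delay	cognitive
ADHD	cognitive
Aggressive behavior	cognitive
Hyperactivity	cognitive
Hypoactivity	cognitive
Sexual impulsivity	cognitive
Stranger anxiety	cognitive
Autism	cognitive
Delirium	cognitive
Intractable seizures	seizure
Irregular EEG	seizure
Hiccups	seizure
Automatisms	seizure
Eye deviation	seizure
Epilepsy	seizure
Myoclonic seizures	seizure
Multifocal clonus	seizure
Brisk reflexes and clonus	muscle_movement
Flexor spasms	muscle_movement
Spasticity	muscle_movement
Reduced deep tendon reflexes	muscle_movement
Inability to walk	muscle_movement
Ataxia	muscle_movement
Choreoathetosis	muscle_movement
Dysdiadochokinesia	muscle_movement
Psychomotor delay	muscle_movement
Severe spastic diplegia	muscle_movement
Global developmental delay	muscle_movement
Hemiparesis	muscle_movement
Hypotonia	muscle_movement
Poor suck/failure to feed	muscle_movement
Dysphagia	muscle_movement
Weak cry	muscle_movement
Lethargy	muscle_movement
Coma	brain_malformation
Hypoplasia of corpus callosum	brain_malformation
Thin corpus callosum	brain_malformation
Agenesis of corpus callosum	brain_malformation
Microcephaly	brain_malformation
Simplified gyral pattern	brain_malformation
Restricted diffusion	brain_malformation
Myelination pattern changes	brain_malformation
Hydrocephaly	brain_malformation
Apnea	respiration
Cyanosis	respiration
Respiratory distress	respiration
Respiratory failure	respiration
Respiratory acidosis	respiration
Hypothyroidism	hormonal
Premature adrenarche	hormonal
Hypoacusis	hearing
Optic atrophy	eyesight
Nystagmus	eyesight
Pyrexia	immune
Hypertrophic pyloric stenosis	digestion
Hyperglycinemia	hyperglycinemia
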
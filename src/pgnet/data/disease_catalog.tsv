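# Canonical cardiovascular disease catalog (23 phenotype labels).
# "merges" lists raw literature labels folded into the canonical label.
label	merges
Heart failure	Acute heart failure;Chronic heart failure
Myocardial infarction	Acute myocardial infarction
Atherosclerosis
Coronary artery disease	Coronary heart disease
Hypertension	Essential hypertension
Pulmonary arterial hypertension	Pulmonary hypertension
Cardiomyopathy	Dilated cardiomyopathy;Hypertrophic cardiomyopathy
Cardiac hypertrophy
Myocarditis	Viral myocarditis
Atrial fibrillation
Arrhythmia
Stroke	Ischemic stroke;Acute ischemic stroke
Aortic aneurysm	Abdominal aortic aneurysm
Aortic stenosis
Peripheral artery disease
Venous thrombosis	Deep vein thrombosis
Pericarditis
Endocarditis	Infective endocarditis
Rheumatic heart disease
Congenital heart disease
Kawasaki disease
Carotid artery disease	Carotid plaque rupture
Others	Unspecified cardiovascular disease
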